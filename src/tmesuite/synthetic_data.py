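"""Synthetic bulk and single-cell cohorts with known ground truth.

The bulk generator plants ``k_true`` latent tumor-microenvironment subtypes:
each subtype activates a distinct subset of gene signatures (round-robin
assignment of signatures to subtypes), active genes get a mean shift of
``effect_size`` log2 units on top of a shared baseline, and Gaussian noise is
added and truncated at zero so the matrix stays non-negative for NMF.
Survival times are exponential with subtype-specific multiplicative hazards —
proportional hazards hold exactly, so Cox recovery tests have a known truth —
and censoring is an independent exponential tuned to the target censoring
fraction.

The single-cell generator draws negative-binomial background counts, plants
marker genes (fold-change up-weighted within their cell type), mitochondrial
genes ("MT-" prefix) tuned to a target count fraction, a set of low-quality
cells (high mitochondrial fraction, < 100 expressed genes), and
ligand-receptor co-expression between chosen sender/receiver cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_core import ExpressionMatrix, SignatureCollection, SurvivalTable, ValidationError

__all__ = [
    "BulkSimConfig",
    "SCSimConfig",
    "GroundTruth",
    "gen_bulk_cohort",
    "gen_sc_cohort",
]


@dataclass
class BulkSimConfig:
    """Parameters of the planted-subtype bulk cohort.

    Defaults give five well-separated subtypes of 60 samples each over 50
    signatures — a desk-scale stand-in for a multi-series microarray training
    cohort with a clear five-subtype structure.
    """

    k_true: int = 5
    n_per_subtype: int = 60
    n_signatures: int = 50
    genes_per_signature: int = 10
    effect_size: float = 3.0       # log2-units mean shift on active genes
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    censor_rate: float = 0.3
    subtype_log_hazards: tuple[float, ...] | None = None
    base_hazard: float = 0.02      # events per month for a log-hazard-0 subtype
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValidationError("k_true must be >= 2")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.subtype_log_hazards is None:
            # spread hazards symmetrically so subtypes differ in prognosis
            self.subtype_log_hazards = tuple(
                np.linspace(-0.7, 0.7, self.k_true).round(6)
            )
        if len(self.subtype_log_hazards) != self.k_true:
            raise ValidationError("subtype_log_hazards must have length k_true")


@dataclass
class SCSimConfig:
    """Parameters of the planted-cell-type single-cell cohort."""

    n_cell_types: int = 4
    cells_per_type: int = 150
    n_genes: int = 1200
    markers_per_type: int = 20
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0     # NB size parameter; smaller = more overdispersed
    marker_fold: float = 8.0
    mito_fraction_good: float = 0.02
    mito_fraction_bad: float = 0.3
    n_mito_genes: int = 10
    n_lowquality_cells: int = 10
    lowquality_expressed_genes: int = 60
    planted_pairs: tuple[tuple[str, str, int, int, float], ...] = (
        ("LIG1", "REC1", 0, 1, 8.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must be > 1")
        for frac in (self.mito_fraction_good, self.mito_fraction_bad):
            if not 0 <= frac <= 1:
                raise ValidationError("mitochondrial fractions must be in [0, 1]")
        if self.lowquality_expressed_genes >= 100:
            raise ValidationError("low-quality cells must express < 100 genes")
        for lig, rec, sender, receiver, fold in self.planted_pairs:
            if not (0 <= sender < self.n_cell_types and 0 <= receiver < self.n_cell_types):
                raise ValidationError(
                    f"planted pair ({lig},{rec}) references unknown cell type"
                )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    labels: dict[str, int]                      # sample/cell id -> subtype/type index
    active_signatures: dict[int, list[str]] = field(default_factory=dict)
    marker_genes: dict[int, list[str]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, int, int, float]] = field(default_factory=list)
    lowquality_cells: list[str] = field(default_factory=list)


def gen_bulk_cohort(
    cfg: BulkSimConfig,
) -> tuple[ExpressionMatrix, SignatureCollection, SurvivalTable, GroundTruth]:
    """Simulate a bulk cohort with planted subtypes and exponential survival."""
    if cfg.k_true > cfg.n_signatures:
        raise ValidationError("need at least one signature per subtype")
    rng = np.random.default_rng(cfg.seed)

    n_genes = cfg.n_signatures * cfg.genes_per_signature
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sig_names = [f"SIG{i:03d}" for i in range(cfg.n_signatures)]
    sigs = SignatureCollection(
        {
            sig_names[i]: gene_ids[i * cfg.genes_per_signature : (i + 1) * cfg.genes_per_signature]
            for i in range(cfg.n_signatures)
        }
    )
    # round-robin: signature i is active in subtype i mod k
    active = {j: [sig_names[i] for i in range(cfg.n_signatures) if i % cfg.k_true == j]
              for j in range(cfg.k_true)}

    n_samples = cfg.k_true * cfg.n_per_subtype
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    subtype = np.repeat(np.arange(cfg.k_true), cfg.n_per_subtype)

    mean = np.full((n_genes, n_samples), cfg.baseline_mean)
    for j in range(cfg.k_true):
        gene_mask = np.zeros(n_genes, dtype=bool)
        for name in active[j]:
            gidx = [gene_ids.index(g) for g in sigs[name]]
            gene_mask[gidx] = True
        mean[np.ix_(gene_mask, subtype == j)] += cfg.effect_size
    values = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape) if cfg.noise_sd > 0 else mean
    values = np.clip(values, 0.0, None)
    expr = ExpressionMatrix(gene_ids, sample_ids, values)

    log_h = np.asarray(cfg.subtype_log_hazards)[subtype]
    rate = cfg.base_hazard * np.exp(log_h)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        # independent exponential censoring: P(C < T) = rc/(rc+rt) = censor_rate
        rate_c = rate * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / rate_c)
    else:
        t_censor = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    surv = SurvivalTable(sample_ids, time, event)

    truth = GroundTruth(
        labels={s: int(j) for s, j in zip(sample_ids, subtype)},
        active_signatures=active,
    )
    return expr, sigs, surv, truth


def gen_prognostic_scores(
    n_samples: int = 600,
    n_signatures: int = 50,
    n_informative: int = 5,
    beta: float = 0.8,
    censor_rate: float = 0.3,
    base_hazard: float = 0.02,
    seed: int = 0,
):
    """Signature-score cohort in which a few signatures drive survival.

    Scores are independent standard normals; the log hazard of a sample is
    ``beta`` times the sum of its ``n_informative`` planted signature scores
    (the first ones), with exponential event times and independent
    exponential censoring at the target rate.  Returns
    ``(SignatureScoreMatrix, SurvivalTable, planted signature names)``.
    """
    from .signature_scoring import SignatureScoreMatrix

    rng = np.random.default_rng(seed)
    names = [f"SIG{i:03d}" for i in range(n_signatures)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    scores = rng.normal(size=(n_signatures, n_samples))
    lin = beta * scores[:n_informative].sum(axis=0)
    rate = base_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        rate_c = rate * censor_rate / (1.0 - censor_rate)
        t_censor = rng.exponential(1.0 / rate_c)
    else:
        t_censor = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return (
        SignatureScoreMatrix(names, sample_ids, scores),
        SurvivalTable(sample_ids, time, event),
        names[:n_informative],
    )


@dataclass
class SCCountMatrix:
    """Sparse genes x cells integer count matrix with mitochondrial mask."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("count matrix shape does not match identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicated gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicated cell identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")

    @property
    def mito_mask(self) -> np.ndarray:
        return np.array([g.startswith("MT-") for g in self.gene_ids])

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size (dispersion) ``size_param``."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def gen_sc_cohort(cfg: SCSimConfig) -> tuple[SCCountMatrix, GroundTruth]:
    """Simulate a single-cell count matrix with planted cell types.

    Gene layout: per-type marker blocks first, then mitochondrial genes
    (named ``MT-``), then ligand/receptor genes, then background genes.
    """
    rng = np.random.default_rng(cfg.seed)
    n_marker = cfg.n_cell_types * cfg.markers_per_type
    pair_genes = list(dict.fromkeys(
        g for lig, rec, *_ in cfg.planted_pairs for g in (lig, rec)
    ))
    n_named = n_marker + cfg.n_mito_genes + len(pair_genes)
    if n_named >= cfg.n_genes:
        raise ValidationError("n_genes too small for markers + mito + pair genes")

    gene_ids: list[str] = []
    marker_genes: dict[int, list[str]] = {}
    for t in range(cfg.n_cell_types):
        marker_genes[t] = [f"MK{t}_{i:03d}" for i in range(cfg.markers_per_type)]
        gene_ids += marker_genes[t]
    mito_ids = [f"MT-{i}" for i in range(cfg.n_mito_genes)]
    gene_ids += mito_ids
    gene_ids += pair_genes
    gene_ids += [f"BG{i:05d}" for i in range(cfg.n_genes - n_named)]

    n_good = cfg.n_cell_types * cfg.cells_per_type
    n_cells = n_good + cfg.n_lowquality_cells
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    cell_type = np.concatenate([
        np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type),
        np.full(cfg.n_lowquality_cells, -1),
    ])

    # per-gene baseline means drawn from a Gamma so the cohort has a realistic
    # spread of expression levels (a flat baseline would make mean-binned
    # variance trends degenerate); mito genes scaled so their expected count
    # share matches the target fraction for good cells
    base = rng.gamma(shape=0.8, scale=cfg.nb_mean / 0.8, size=cfg.n_genes)
    base = np.maximum(base, 0.05 * cfg.nb_mean)
    # marker and ligand/receptor baselines are shifted upward (still spread):
    # a planted fold-change on a silent gene would be no marker at all
    base[:n_marker] += 0.4 * cfg.nb_mean
    base[n_marker + cfg.n_mito_genes : n_named] += 0.4 * cfg.nb_mean
    gidx = {g: i for i, g in enumerate(gene_ids)}
    mito_idx = np.array([gidx[g] for g in mito_ids])
    non_mito = np.ones(cfg.n_genes, dtype=bool)
    non_mito[mito_idx] = False
    non_mito_total = float(base[non_mito].sum())

    def mito_mean(frac: float) -> float:
        if frac >= 1:
            raise ValidationError("mitochondrial fraction must be < 1")
        return frac / (1 - frac) * non_mito_total / cfg.n_mito_genes

    base[mito_idx] = mito_mean(cfg.mito_fraction_good)

    mean_mat = np.tile(base, (n_cells, 1))  # cells x genes
    for t in range(cfg.n_cell_types):
        rows = cell_type == t
        cols = [gidx[g] for g in marker_genes[t]]
        mean_mat[np.ix_(rows, cols)] *= cfg.marker_fold
    for lig, rec, sender, receiver, fold in cfg.planted_pairs:
        mean_mat[cell_type == sender, gidx[lig]] *= fold
        mean_mat[cell_type == receiver, gidx[rec]] *= fold

    # low-quality cells: high mito fraction, few expressed genes
    lowq = cell_type == -1
    if lowq.any():
        keep = rng.choice(
            np.setdiff1d(np.arange(cfg.n_genes), mito_idx),
            size=cfg.lowquality_expressed_genes - cfg.n_mito_genes,
            replace=False,
        )
        lq_mean = np.zeros(cfg.n_genes)
        lq_mean[keep] = base[keep]
        lq_non_mito = float(base[keep].sum())
        bad = cfg.mito_fraction_bad
        lq_mean[mito_idx] = bad / (1 - bad) * lq_non_mito / cfg.n_mito_genes
        mean_mat[lowq] = lq_mean

    counts = _nb_draw(rng, mean_mat, cfg.nb_dispersion).T  # genes x cells
    mat = SCCountMatrix(gene_ids, cell_ids, sp.csr_matrix(counts))
    truth = GroundTruth(
        labels={c: int(t) for c, t in zip(cell_ids, cell_type)},
        marker_genes=marker_genes,
        planted_pairs=list(cfg.planted_pairs),
        lowquality_cells=[c for c, t in zip(cell_ids, cell_type) if t == -1],
    )
    return mat, truth
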