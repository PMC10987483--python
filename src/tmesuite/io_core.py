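"""Core containers and readers/writers for the formats the suite touches.

Bulk expression comes in as genes x samples TSV (log2(TPM+1) for RNA-seq,
normalized intensities for arrays), gene sets as GMT, survival metadata as a
three-column TSV (sample id, time in months, event indicator).  All readers
validate on construction so downstream stages can assume well-formed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tmesuite")

__all__ = [
    "ExpressionMatrix",
    "SignatureCollection",
    "SurvivalTable",
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_survival_tsv",
    "write_survival_tsv",
]


class ValidationError(ValueError):
    """Raised when an input file or container violates a format invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric expression matrix.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``.  Gene and sample identifiers are unique; all values
    are finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicated gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample identifiers")
        if not all(g for g in self.gene_ids):
            raise ValidationError("empty gene identifier")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class SignatureCollection:
    """Ordered mapping from signature name to its member gene symbols."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"signature {name!r} has no genes")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"signature {name!r} has duplicated genes")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> list[str]:
        return self.entries[name]

    def subset(self, names: list[str]) -> "SignatureCollection":
        return SignatureCollection({n: list(self.entries[n]) for n in names})


@dataclass
class SurvivalTable:
    """Right-censored overall-survival metadata.

    ``time`` is follow-up in months (non-negative); ``event`` is 1 if death
    was observed, 0 if the sample was censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        ev = np.asarray(self.event, dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValidationError("event indicator must be 0 or 1")
        self.event = ev.astype(int)
        if len(self.sample_ids) != self.time.shape[0] or self.time.shape != self.event.shape:
            raise ValidationError("survival table fields have mismatched lengths")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample identifiers in survival table")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("survival times must be finite and >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def align(self, sample_ids: list[str]) -> "SurvivalTable":
        """Reorder/subset to ``sample_ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples missing from survival table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return SurvivalTable(list(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass
class RunConfig:
    """Parameters and master seed for a full pipeline run.

    Every stochastic stage receives a child seed spawned deterministically
    from ``seed``, so a run is fully replayable from this object alone.
    """

    seed: int = 0
    # subtype discovery
    k_range: tuple[int, int] = (3, 8)
    n_runs_survey: int = 50
    n_runs_final: int = 500
    nmf_max_iter: int = 2000
    nmf_max_iter_survey: int = 500
    nmf_tol: float = 1e-6
    # preprocessing
    min_genes_found: int = 2
    min_abs_cor: float = 0.3
    outlier_max_fraction: float = 0.02
    # feature selection
    lasso_n_folds: int = 10
    rf_n_trees: int = 1000
    rf_top_n: int = 30
    svm_drop_fraction: float = 0.1
    # single cell
    qc_min_cells: int = 5
    qc_min_genes: int = 100
    qc_max_mito: float = 0.05
    n_hvg: int = 2000
    n_pcs: int = 20
    k_neighbors: int = 20
    resolution: float = 0.8
    # interactions
    n_permutations: int = 1000
    min_fraction: float = 0.1

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2**31) derived from the master seed."""
        ss = np.random.SeedSequence([self.seed, _stable_hash(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(stage))


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path, aggregate_duplicates: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header = sample ids).

    With ``aggregate_duplicates`` duplicate gene rows are collapsed by their
    mean, matching the mean-based signature scoring downstream; otherwise a
    duplicated symbol is an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.index.duplicated().any():
        if not aggregate_duplicates:
            dups = sorted(set(numeric.index[numeric.index.duplicated()]))
            raise ValidationError(f"{path}: duplicated gene symbols {dups[:5]}")
        numeric = numeric.groupby(level=0, sort=False).mean()
        logger.info("collapsed duplicate gene symbols by mean in %s", path)
    return ExpressionMatrix(
        [str(g) for g in numeric.index],
        [str(s) for s in numeric.columns],
        numeric.values.astype(float),
    )


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> SignatureCollection:
    """Read a GMT gene-set file (name, description, genes; tab-separated).

    The description field is discarded; signature order is preserved; genes
    repeated within a line are de-duplicated keeping first occurrence.
    """
    entries: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in entries:
                raise ValidationError(f"{path}:{lineno}: duplicated signature name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValidationError(f"{path}:{lineno}: signature {name!r} has no genes")
            entries[name] = genes
    if not entries:
        raise ValidationError(f"{path}: no signatures found")
    return SignatureCollection(entries)


def write_gmt(sigs: SignatureCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sigs.entries.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_survival_tsv(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: survival table needs columns {sorted(required)}")
    return SurvivalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
    )


def write_survival_tsv(surv: SurvivalTable, path) -> None:
    surv.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_table(df: pd.DataFrame, path) -> None:
    """Write any tabular result as TSV at full precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
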