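"""Signature scoring and training-cohort preprocessing.

A signature score is the arithmetic mean of a sample's expression over the
signature's member genes that are present in the matrix.  Preprocessing
mirrors the subtyping workflow: (1) score all signatures, (2) drop outlier
samples found by hierarchical clustering of score profiles, (3) keep only
signatures that correlate robustly with at least one other signature, and
(4) screen each retained signature for prognostic association with a
univariate Cox model on standardized (per-SD) scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import (
    ExpressionMatrix,
    SignatureCollection,
    SurvivalTable,
    ValidationError,
)
from .survival_analysis import cox_univariate

logger = logging.getLogger("tmesuite")

__all__ = [
    "SignatureScoreMatrix",
    "CoxScreenResult",
    "score_signatures",
    "detect_outlier_samples",
    "filter_signatures_by_correlation",
    "cox_screen",
]


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples matrix of mean-expression scores."""

    signature_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.signature_names), len(self.sample_ids)):
            raise ValidationError("score matrix shape does not match names")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("non-finite signature scores")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.signature_names, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "SignatureScoreMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SignatureScoreMatrix(list(self.signature_names), list(sample_ids),
                                    self.scores[:, idx])

    def subset_signatures(self, names: list[str]) -> "SignatureScoreMatrix":
        pos = {n: i for i, n in enumerate(self.signature_names)}
        idx = [pos[n] for n in names]
        return SignatureScoreMatrix(list(names), list(self.sample_ids), self.scores[idx])


@dataclass
class CoxScreenResult:
    """Univariate Cox screen over signatures (per-SD hazard ratios)."""

    table: pd.DataFrame  # signature, hazard_ratio, ci_low, ci_high, p_value, direction

    @property
    def protective(self) -> list[str]:
        t = self.table
        return list(t.loc[t["direction"] == "protective", "signature"])

    @property
    def unfavorable(self) -> list[str]:
        t = self.table
        return list(t.loc[t["direction"] == "unfavorable", "signature"])


def score_signatures(
    expr: ExpressionMatrix,
    sigs: SignatureCollection,
    min_genes_found: int = 2,
) -> SignatureScoreMatrix:
    """Mean expression of each signature's matched genes per sample.

    Signatures with fewer than ``min_genes_found`` genes present in the
    matrix are dropped (logged); an error is raised if none survive.
    """
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    names, rows = [], []
    for name, genes in sigs.entries.items():
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if len(idx) < min_genes_found:
            logger.info("signature %r dropped: %d matched genes < %d",
                        name, len(idx), min_genes_found)
            continue
        names.append(name)
        rows.append(expr.values[idx].mean(axis=0))
    if not names:
        raise ValidationError("no signature has enough matched genes")
    return SignatureScoreMatrix(names, list(expr.sample_ids), np.vstack(rows))


def _correlation_distance(scores: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample profiles (columns)."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(scores.T)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def detect_outlier_samples(
    scores: SignatureScoreMatrix,
    max_fraction: float = 0.02,
    min_separation: float = 0.5,
) -> list[str]:
    """Outlier samples by average-linkage clustering of score profiles.

    Samples are clustered on distance 1 - Pearson(profiles) and cut into two
    clusters; if the smaller cluster holds fewer than ``max_fraction`` of the
    samples AND is genuinely separated (mean cross-cluster distance at least
    ``min_separation``, i.e. mean correlation with the majority below 0.5),
    its members are outliers and the cut repeats once on the rest.  The
    separation guard keeps the arbitrary top split of a homogeneous cohort
    (where all profiles correlate near 1) from flagging spurious singletons.
    Samples with constant (zero-variance) profiles are flagged directly.
    """
    if scores.n_samples < 10:
        raise ValidationError("outlier detection needs >= 10 samples")
    sample_ids = np.array(scores.sample_ids)
    constant = scores.scores.std(axis=0) == 0
    outliers = list(sample_ids[constant])
    if outliers:
        logger.warning("flagging %d constant-profile samples as outliers", len(outliers))
    active = ~constant

    for _ in range(2):  # initial cut plus at most one repeat
        ids = sample_ids[active]
        if len(ids) < 4:
            break
        d = _correlation_distance(scores.scores[:, active])
        z = linkage(squareform(d, checks=False), method="average")
        assign = fcluster(z, t=2, criterion="maxclust")
        sizes = np.bincount(assign)[1:]
        if len(sizes) < 2:
            break
        minority = int(np.argmin(sizes)) + 1
        if sizes[minority - 1] >= max_fraction * len(ids):
            break
        cross = d[np.ix_(assign == minority, assign != minority)]
        if cross.mean() < min_separation:
            break
        flagged = ids[assign == minority]
        outliers.extend(flagged)
        drop = np.isin(sample_ids, flagged)
        active = active & ~drop
    return list(outliers)


def filter_signatures_by_correlation(
    scores: SignatureScoreMatrix,
    min_abs_cor: float = 0.3,
) -> list[str]:
    """Signatures whose best absolute correlation with another signature
    reaches ``min_abs_cor`` (order preserved).

    Zero-variance signatures correlate 0 with everything (logged) and are
    therefore dropped at any positive threshold.
    """
    if scores.n_signatures < 2:
        raise ValidationError("correlation filter needs >= 2 signatures")
    sd = scores.scores.std(axis=1)
    if np.any(sd == 0):
        logger.warning("%d zero-variance signatures treated as correlation 0",
                       int((sd == 0).sum()))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(scores.scores)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    best = np.abs(corr).max(axis=1)
    return [n for n, b in zip(scores.signature_names, best) if b >= min_abs_cor]


def cox_screen(scores: SignatureScoreMatrix, surv: SurvivalTable,
               alpha: float = 0.05) -> CoxScreenResult:
    """Univariate Cox fit per signature on per-signature standardized scores.

    Direction is 'protective' for HR < 1 with p < alpha, 'unfavorable' for
    HR > 1 with p < alpha, 'neutral' otherwise (including zero-variance or
    non-converged fits).
    """
    surv = surv.align(scores.sample_ids)
    if surv.event.sum() < 2:
        raise ValidationError("Cox screen needs >= 2 events")
    rows = []
    for i, name in enumerate(scores.signature_names):
        x = scores.scores[i]
        sd = x.std()
        if sd == 0:
            rows.append((name, 1.0, 1.0, 1.0, 1.0, "neutral"))
            continue
        fit = cox_univariate((x - x.mean()) / sd, surv)
        if not fit.converged:
            rows.append((name, 1.0, 1.0, 1.0, 1.0, "neutral"))
            continue
        if fit.p_value < alpha:
            direction = "protective" if fit.hazard_ratio < 1 else "unfavorable"
        else:
            direction = "neutral"
        rows.append((name, fit.hazard_ratio, fit.ci_low, fit.ci_high, fit.p_value, direction))
    table = pd.DataFrame(
        rows, columns=["signature", "hazard_ratio", "ci_low", "ci_high", "p_value", "direction"]
    )
    return CoxScreenResult(table)
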