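"""Nearest-centroid projection of trained subtypes onto external cohorts.

Training centroids are per-subtype means of z-scored signature scores.  A
new cohort is z-scored per signature *within itself* and each sample is
assigned the centroid with the highest Pearson correlation over the shared
signatures.  Cohort-wise standardization plus correlation makes the
projection invariant to per-signature affine rescaling of the new cohort,
which is what allows transfer across platforms (microarray vs RNA-seq).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import ValidationError
from .signature_scoring import SignatureScoreMatrix
from .subtype_discovery import SubtypeAssignment

logger = logging.getLogger("tmesuite")

__all__ = ["SubtypeCentroids", "compute_centroids", "assign_subtype"]


@dataclass
class SubtypeCentroids:
    subtype_labels: list[int]        # 1..k
    signature_names: list[str]
    centroids: np.ndarray            # k x signatures, z-score units
    train_mean: np.ndarray           # per-signature standardization parameters
    train_sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.subtype_labels) < 2:
            raise ValidationError("need at least 2 subtypes")
        if np.any(self.train_sd <= 0):
            raise ValidationError("zero-variance signature in training scores")


def compute_centroids(
    scores: SignatureScoreMatrix, labels: SubtypeAssignment
) -> SubtypeCentroids:
    """Per-subtype mean z-scored profile of the training cohort."""
    if scores.sample_ids != labels.sample_ids:
        scores = scores.subset_samples(labels.sample_ids)
    mean = scores.scores.mean(axis=1)
    sd = scores.scores.std(axis=1)
    if np.any(sd == 0):
        bad = [n for n, s in zip(scores.signature_names, sd) if s == 0]
        raise ValidationError(f"zero-variance signatures: {bad[:5]}")
    z = (scores.scores - mean[:, None]) / sd[:, None]
    subtypes = sorted(set(labels.labels.tolist()))
    cents = []
    for j in subtypes:
        mask = labels.labels == j
        if mask.sum() < 2:
            raise ValidationError(f"subtype {j} has fewer than 2 samples")
        cents.append(z[:, mask].mean(axis=1))
    return SubtypeCentroids(
        subtype_labels=[int(j) for j in subtypes],
        signature_names=list(scores.signature_names),
        centroids=np.vstack(cents),
        train_mean=mean,
        train_sd=sd,
    )


def assign_subtype(
    new_scores: SignatureScoreMatrix,
    centroids: SubtypeCentroids,
    min_overlap: float = 0.8,
) -> tuple[SubtypeAssignment, np.ndarray]:
    """Assign each new sample to the best-correlated centroid.

    Returns the assignment and the per-sample correlation with the chosen
    centroid (a QC measure: low values flag samples that match no subtype).
    """
    shared = [n for n in centroids.signature_names if n in new_scores.signature_names]
    missing = [n for n in centroids.signature_names if n not in shared]
    if len(shared) < min_overlap * len(centroids.signature_names):
        raise ValidationError(
            f"only {len(shared)}/{len(centroids.signature_names)} centroid signatures "
            f"present in the new cohort; missing e.g. {missing[:5]}"
        )
    if missing:
        logger.info("projection uses %d/%d shared signatures",
                    len(shared), len(centroids.signature_names))
    sub = new_scores.subset_signatures(shared)
    cent_idx = [centroids.signature_names.index(n) for n in shared]
    cents = centroids.centroids[:, cent_idx]

    mean = sub.scores.mean(axis=1)
    sd = sub.scores.std(axis=1)
    sd[sd == 0] = 1.0  # flat signature contributes nothing after centering
    z = (sub.scores - mean[:, None]) / sd[:, None]  # signatures x samples

    zc = z - z.mean(axis=0, keepdims=True)
    cc = cents - cents.mean(axis=1, keepdims=True)
    denom = np.sqrt((zc**2).sum(axis=0))[None, :] * np.sqrt((cc**2).sum(axis=1))[:, None]
    denom[denom == 0] = np.inf
    corr = (cc @ zc) / denom  # k x samples
    best = np.argmax(corr, axis=0)  # smallest index on ties
    labels = np.array([centroids.subtype_labels[b] for b in best])
    best_corr = corr[best, np.arange(corr.shape[1])]
    return SubtypeAssignment(list(new_scores.sample_ids), labels), best_corr
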