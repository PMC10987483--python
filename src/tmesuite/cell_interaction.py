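"""Ligand-receptor interaction scoring with cluster-label permutation tests.

For a pair (ligand L, receptor R) and an ordered cluster pair (sender,
receiver), the interaction score is the mean of the two group means:
(mean L in sender + mean R in receiver) / 2 on log-normalized expression.
Significance is assessed by permuting the cluster labels of all cells
(the same permutation set is reused across pairs, so a whole run is
deterministic given the seed) and counting permuted scores at least as
large as the observed one, with the add-one convention so the smallest
attainable p is 1/(1+n_perm).  Triples in which either gene is expressed in
less than ``min_fraction`` of its cluster's cells are gated out as untested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_core import ValidationError
from .scrna_pipeline import CellClustering, SCExpression

logger = logging.getLogger("tmesuite")

__all__ = [
    "LRPairTable",
    "interaction_score",
    "permutation_test",
    "interaction_network_summary",
]


@dataclass
class LRPairTable:
    """Rows of (ligand gene, receptor gene, pair name)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ligand", "receptor", "pair"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"LR pair table needs columns {sorted(required)}")
        if self.table["pair"].duplicated().any():
            raise ValidationError("duplicated pair names")
        if (self.table["ligand"].eq("") | self.table["receptor"].eq("")).any():
            raise ValidationError("empty gene name in LR pair table")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "LRPairTable":
        return cls(pd.DataFrame(
            {"ligand": [l for l, _ in pairs],
             "receptor": [r for _, r in pairs],
             "pair": [f"{l}|{r}" for l, r in pairs]}
        ))

    @classmethod
    def read_tsv(cls, path) -> "LRPairTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def _group_stats(values: sp.csr_matrix, gene_idx: int, mask: np.ndarray
                 ) -> tuple[float, float]:
    row = np.asarray(values[gene_idx].todense()).ravel()
    sub = row[mask]
    return float(sub.mean()), float((sub > 0).mean())


def interaction_score(
    norm: SCExpression,
    clustering: CellClustering,
    ligand: str,
    receptor: str,
    sender: int,
    receiver: int,
) -> dict:
    """Observed score and expressed fractions for one triple."""
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    for gene in (ligand, receptor):
        if gene not in pos:
            return {"score": np.nan, "tested": False,
                    "reason": f"gene {gene!r} absent"}
    send_mask = clustering.clusters == sender
    recv_mask = clustering.clusters == receiver
    if not send_mask.any() or not recv_mask.any():
        raise ValidationError("empty sender or receiver cluster")
    lig_mean, lig_frac = _group_stats(norm.values, pos[ligand], send_mask)
    rec_mean, rec_frac = _group_stats(norm.values, pos[receptor], recv_mask)
    return {
        "score": (lig_mean + rec_mean) / 2.0,
        "expressed_fraction_ligand": lig_frac,
        "expressed_fraction_receptor": rec_frac,
        "tested": True,
    }


def permutation_test(
    norm: SCExpression,
    clustering: CellClustering,
    pairs: LRPairTable,
    n_perm: int = 1000,
    min_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values for every (pair, sender, receiver) triple.

    Returns one row per triple with the observed score, expressed fractions,
    tested flag and p-value (NaN where the expression gate failed or a gene
    is absent).
    """
    if clustering.n_clusters < 2:
        raise ValidationError("permutation test needs >= 2 clusters")
    if n_perm < 100:
        logger.warning("n_perm=%d gives coarse p-value granularity", n_perm)
    rng = np.random.default_rng(seed)
    n_cells = len(clustering.cell_ids)
    n_clusters = clustering.n_clusters

    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    genes = list(dict.fromkeys(
        g for _, row in pairs.table.iterrows() for g in (row["ligand"], row["receptor"])
        if g in pos
    ))
    gdx = {g: i for i, g in enumerate(genes)}
    expr = np.asarray(norm.values[[pos[g] for g in genes]].todense(), dtype=float) \
        if genes else np.zeros((0, n_cells))

    def cluster_means(labels: np.ndarray) -> np.ndarray:
        ind = sp.csr_matrix(
            (np.ones(n_cells), (labels, np.arange(n_cells))),
            shape=(n_clusters, n_cells),
        )
        sizes = np.maximum(np.asarray(ind.sum(axis=1)).ravel(), 1)
        return (ind @ expr.T) / sizes[:, None]  # clusters x genes

    obs_means = cluster_means(clustering.clusters)
    obs_fracs = np.zeros_like(obs_means)
    for cl in range(n_clusters):
        mask = clustering.clusters == cl
        obs_fracs[cl] = (expr[:, mask] > 0).mean(axis=1) if mask.any() else 0.0

    # same permutations reused for every pair
    perms = [rng.permutation(clustering.clusters) for _ in range(n_perm)]
    perm_means = np.stack([cluster_means(p) for p in perms])  # n_perm x clusters x genes

    rows = []
    for _, pr in pairs.table.iterrows():
        lig, rec, name = pr["ligand"], pr["receptor"], pr["pair"]
        present = lig in pos and rec in pos
        for sender in range(n_clusters):
            for receiver in range(n_clusters):
                if not present:
                    rows.append((name, sender, receiver, np.nan, np.nan, np.nan,
                                 False, np.nan, "gene absent"))
                    continue
                li, ri = gdx[lig], gdx[rec]
                lig_frac = obs_fracs[sender, li]
                rec_frac = obs_fracs[receiver, ri]
                score = (obs_means[sender, li] + obs_means[receiver, ri]) / 2.0
                if lig_frac < min_fraction or rec_frac < min_fraction:
                    rows.append((name, sender, receiver, score, lig_frac, rec_frac,
                                 False, np.nan, "expression gate"))
                    continue
                null = (perm_means[:, sender, li] + perm_means[:, receiver, ri]) / 2.0
                p = (1.0 + np.sum(null >= score - 1e-12)) / (1.0 + n_perm)
                rows.append((name, sender, receiver, score, lig_frac, rec_frac,
                             True, p, ""))
    return pd.DataFrame(
        rows,
        columns=["pair", "sender", "receiver", "score",
                 "expressed_fraction_ligand", "expressed_fraction_receptor",
                 "tested", "p_value", "reason"],
    )


def interaction_network_summary(results: pd.DataFrame, alpha: float = 0.05
                                ) -> pd.DataFrame:
    """Count of significant tested triples per ordered (sender, receiver) pair."""
    tested = results[results["tested"].astype(bool)]
    senders = sorted(results["sender"].unique())
    receivers = sorted(results["receiver"].unique())
    rows = []
    for s in senders:
        for r in receivers:
            sub = tested[(tested["sender"] == s) & (tested["receiver"] == r)]
            rows.append((s, r, int((sub["p_value"] < alpha).sum())))
    return pd.DataFrame(rows, columns=["sender", "receiver", "n_significant"])
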