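"""Tri-algorithm prognostic-signature selection.

Three selectors run on the signatures x samples score matrix and their
results are intersected:

* LASSO-Cox — an L1-penalized Cox model over a 100-point log-spaced lambda
  path, with the penalty chosen by 10-fold cross-validated partial-likelihood
  deviance (folds stratified by event status); the selected set is the
  signatures with nonzero coefficients at the optimum.
* Random forest — a bagged ensemble of decision trees classifying a binary
  prognosis label; signatures are ranked both by mean impurity (Gini)
  importance and by out-of-bag permutation-accuracy importance, and the
  intersection of the two top-n lists is selected.
* SVM-RFE — recursive feature elimination with a linear max-margin
  classifier, dropping the lowest-squared-weight fraction each round; the
  returned set is the smallest candidate set within one standard error of
  the best cross-validated accuracy.

The random forest and SVM are classifiers, so survival data is reduced to a
binary label — survival status at the cohort's median follow-up: samples
that died by then are "poor", samples followed past it are "good", and
samples censored earlier (status unknown at the horizon) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_core import SurvivalTable, ValidationError
from .signature_scoring import SignatureScoreMatrix
from .survival_analysis import breslow_loglik

logger = logging.getLogger("tmesuite")

__all__ = [
    "SelectionResult",
    "binary_outcome",
    "lasso_cox_select",
    "rf_select",
    "svm_rfe_select",
    "select_signatures",
    "intersect_selections",
]


@dataclass
class SelectionResult:
    lasso_set: list[str]
    rf_set: list[str]
    svmrfe_set: list[str]
    intersection: list[str]
    diagnostics: dict = field(default_factory=dict)


def _standardize(scores: SignatureScoreMatrix) -> np.ndarray:
    x = scores.scores.T.astype(float)  # samples x signatures
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def binary_outcome(surv: SurvivalTable) -> tuple[np.ndarray, np.ndarray]:
    """(kept sample mask, label): survival status at the median follow-up.

    With t* the cohort's median follow-up time, a sample is labeled 1
    ("poor") if it died at or before t* and 0 ("good") if it was followed
    past t*; samples censored at or before t* have an unknown status at the
    horizon and are excluded.  Anchoring the horizon at the median keeps the
    classes roughly balanced, which accuracy-driven selectors need.
    """
    median_fu = float(np.median(surv.time))
    died_early = (surv.event == 1) & (surv.time <= median_fu)
    alive_past = surv.time > median_fu
    keep = died_early | alive_past
    y = died_early[keep].astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("binary prognosis outcome is degenerate (one class)")
    return keep, y


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------

def lasso_cox_select(
    scores: SignatureScoreMatrix,
    surv: SurvivalTable,
    n_folds: int = 10,
    n_alphas: int = 100,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Signatures with nonzero LASSO-Cox coefficients at the CV-optimal penalty.

    Cross-validated deviance uses the Verweij & Van Houwelingen form
    -2 * [ ll_full(beta_train) - ll_train(beta_train) ] summed over folds,
    with the Breslow partial likelihood.
    """
    surv = surv.align(scores.sample_ids)
    if surv.event.sum() < n_folds:
        raise ValidationError("need at least one event per CV fold")
    x = _standardize(scores)
    y = Surv.from_arrays(surv.event.astype(bool), surv.time)

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.001, fit_baseline_model=False
    )
    path_model.fit(x, y)
    alphas = path_model.alphas_

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviance = np.zeros(len(alphas))
    for train_idx, _ in cv.split(x, surv.event):
        fold_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                            fit_baseline_model=False)
        fold_model.fit(x[train_idx], y[train_idx])
        coefs = fold_model.coef_  # features x n_fitted_alphas
        fitted = list(fold_model.alphas_)
        for ai, alpha in enumerate(alphas):
            beta = coefs[:, fitted.index(alpha)] if alpha in fitted else coefs[:, -1]
            ll_full = breslow_loglik(x, surv.time, surv.event, beta)
            ll_train = breslow_loglik(x[train_idx], surv.time[train_idx],
                                      surv.event[train_idx], beta)
            deviance[ai] += -2.0 * (ll_full - ll_train)
    best_idx = int(np.argmin(deviance))
    beta_star = path_model.coef_[:, best_idx]
    selected = [n for n, b in zip(scores.signature_names, beta_star) if b != 0.0]
    if not selected:
        logger.warning("LASSO-Cox selected no signatures at the CV optimum")
    diagnostics = {
        "alphas": alphas.tolist(),
        "cv_deviance": deviance.tolist(),
        "alpha_star": float(alphas[best_idx]),
        "n_nonzero_path": (path_model.coef_ != 0).sum(axis=0).tolist(),
    }
    return selected, diagnostics


# ---------------------------------------------------------------------------
# Random forest with OOB permutation importance
# ---------------------------------------------------------------------------

def rf_select(
    scores: SignatureScoreMatrix,
    surv: SurvivalTable | None = None,
    n_trees: int = 1000,
    top_n: int = 30,
    seed: int = 0,
    outcome: np.ndarray | None = None,
) -> tuple[list[str], dict]:
    """Intersection of the Gini-importance and OOB-permutation top-n lists.

    Trees are grown on bootstrap samples; permutation importance for a
    signature is the mean over trees of the drop in out-of-bag accuracy when
    that signature's OOB values are permuted.  Pass ``outcome`` to override
    the survival-derived binary label.
    """
    if scores.n_samples < 50:
        raise ValidationError("random-forest selection needs >= 50 samples")
    x = scores.scores.T
    if outcome is None:
        if surv is None:
            raise ValidationError("need either survival data or an outcome vector")
        keep, y = binary_outcome(surv.align(scores.sample_ids))
        x = x[keep]
    else:
        y = np.asarray(outcome, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValidationError("binary outcome is degenerate (one class)")
    n, p = x.shape
    rng = np.random.default_rng(seed)

    gini = np.zeros(p)
    perm_drop = np.zeros(p)
    perm_counts = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(x[boot], y[boot])
        gini += tree.feature_importances_
        if oob.size == 0 or len(np.unique(y[oob])) == 0:
            continue
        x_oob = x[oob]
        acc = (tree.predict(x_oob) == y[oob]).mean()
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size:
            # one batched predict over all per-feature permuted copies
            m = oob.size
            stacked = np.repeat(x_oob[None, :, :], used.size, axis=0)
            for bi, f in enumerate(used):
                stacked[bi, :, f] = x_oob[rng.permutation(m), f]
            preds = tree.predict(stacked.reshape(-1, p)).reshape(used.size, m)
            acc_perm = (preds == y[oob][None, :]).mean(axis=1)
            perm_drop[used] += acc - acc_perm
            perm_counts[used] += 1
        perm_counts[np.setdiff1d(np.arange(p), used)] += 1  # unused: drop 0
    gini /= n_trees
    perm_imp = np.divide(perm_drop, np.maximum(perm_counts, 1))

    order_gini = np.argsort(-gini, kind="stable")[:top_n]
    order_perm = np.argsort(-perm_imp, kind="stable")[:top_n]
    names = scores.signature_names
    top_gini = [names[i] for i in order_gini]
    top_perm = [names[i] for i in order_perm]
    selected = [n_ for n_ in names if n_ in set(top_gini) and n_ in set(top_perm)]
    diagnostics = {
        "gini_importance": dict(zip(names, gini.tolist())),
        "oob_permutation_importance": dict(zip(names, perm_imp.tolist())),
        "top_gini": top_gini,
        "top_permutation": top_perm,
    }
    return selected, diagnostics


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def svm_rfe_select(
    scores: SignatureScoreMatrix,
    surv: SurvivalTable | None = None,
    drop_fraction: float = 0.1,
    c: float = 1.0,
    n_cv_folds: int = 5,
    seed: int = 0,
    outcome: np.ndarray | None = None,
) -> tuple[list[str], dict]:
    """Recursive feature elimination with a linear max-margin classifier.

    Each round drops the ceil(drop_fraction * remaining) features with the
    smallest squared weights (constant features are dropped first, with a
    warning).  Candidate sets along the path are scored by stratified k-fold
    CV accuracy; the smallest set within one standard error of the best
    accuracy is returned.
    """
    x_all = _standardize(scores)
    if outcome is None:
        if surv is None:
            raise ValidationError("need either survival data or an outcome vector")
        keep, y = binary_outcome(surv.align(scores.sample_ids))
        x_all = x_all[keep]
    else:
        y = np.asarray(outcome, dtype=int)
    names = list(scores.signature_names)

    constant = np.ptp(x_all, axis=0) == 0
    if constant.any():
        logger.warning("dropping %d constant signatures before RFE", int(constant.sum()))
    remaining = [i for i in range(len(names)) if not constant[i]]
    # alphabetical order makes the all-identical tie-break deterministic
    remaining.sort(key=lambda i: names[i])

    cv = StratifiedKFold(n_splits=n_cv_folds, shuffle=True, random_state=seed)
    path = []  # (feature index list, cv accuracy, cv se)
    elimination_order: list[str] = []
    while remaining:
        xs = x_all[:, remaining]
        accs = []
        for tr, te in cv.split(xs, y):
            clf = LinearSVC(C=c, random_state=seed)
            clf.fit(xs[tr], y[tr])
            accs.append((clf.predict(xs[te]) == y[te]).mean())
        accs = np.asarray(accs)
        path.append((list(remaining), float(accs.mean()),
                     float(accs.std(ddof=1) / np.sqrt(len(accs)))))
        if len(remaining) == 1:
            elimination_order.append(names[remaining[0]])
            break
        clf = LinearSVC(C=c, random_state=seed)
        clf.fit(xs, y)
        w2 = np.ravel(clf.coef_) ** 2
        n_drop = int(np.ceil(drop_fraction * len(remaining)))
        drop_local = np.argsort(w2, kind="stable")[:n_drop]
        dropped = [remaining[i] for i in sorted(drop_local)]
        elimination_order.extend(names[i] for i in dropped)
        remaining = [f for i, f in enumerate(remaining) if i not in set(drop_local)]

    best_acc = max(acc for _, acc, _ in path)
    best_se = min(se for _, acc, se in path if acc == best_acc)
    eligible = [(feats, acc) for feats, acc, _ in path if acc >= best_acc - best_se]
    feats_star = min(eligible, key=lambda t: len(t[0]))[0]
    selected = [n_ for n_ in names if n_ in {names[i] for i in feats_star}]
    diagnostics = {
        "path": [{"n_features": len(f), "cv_accuracy": a, "cv_se": s}
                 for f, a, s in path],
        "elimination_order": elimination_order,
    }
    return selected, diagnostics


def intersect_selections(lasso_set: list[str], rf_set: list[str],
                         svmrfe_set: list[str], order: list[str]) -> list[str]:
    """Three-way intersection, ordered by the input signature order."""
    common = set(lasso_set) & set(rf_set) & set(svmrfe_set)
    return [n for n in order if n in common]


def select_signatures(
    scores: SignatureScoreMatrix,
    surv: SurvivalTable,
    n_folds: int = 10,
    n_trees: int = 1000,
    top_n: int = 30,
    drop_fraction: float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Run all three selectors and intersect their sets."""
    lasso, d_lasso = lasso_cox_select(scores, surv, n_folds=n_folds, seed=seed)
    rf, d_rf = rf_select(scores, surv, n_trees=n_trees, top_n=top_n, seed=seed + 1)
    svm, d_svm = svm_rfe_select(scores, surv, drop_fraction=drop_fraction, seed=seed + 2)
    inter = intersect_selections(lasso, rf, svm, scores.signature_names)
    return SelectionResult(lasso, rf, svm, inter,
                           {"lasso": d_lasso, "rf": d_rf, "svmrfe": d_svm})
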