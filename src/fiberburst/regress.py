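"""Per-fiber transcription-state regression on CRE accessibility.

For each gene and state, an L1-penalized logistic regression
(C=1.0, balanced class weights, liblinear, max_iter=500) maps the binary
CRE-accessibility feature matrix to the state flag. Performance is
out-of-fold AUC from stratified K-fold CV; feature importance is the drop
in OOF AUC when a feature (or subset) is removed with fold assignments
held fixed, and Synergy(S) = sum_i dAUC_i - dAUC_S quantifies
cooperativity (negative => cooperative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

EMPTY_MODEL_AUC = 0.5  # convention when dropout leaves zero features


@dataclass
class RegressionModel:
    gene_id: str
    state: str
    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    converged: bool = True


@dataclass
class ModelEvaluation:
    auc: float
    average_precision: float
    null_aucs: np.ndarray
    delta_auc: float
    single_feature_aucs: dict[str, float] = field(default_factory=dict)
    dropout_delta_auc: dict[str, float] = field(default_factory=dict)
    k_used: int = 0
    seed: int = 0


@dataclass
class SynergyResult:
    subset: tuple[str, ...]
    k: int
    synergy: float
    delta_auc_subset: float
    singleton_sum: float
    null_synergies: np.ndarray | None = None


def _make_estimator(seed: int) -> LogisticRegression:
    # L1 penalty via l1_ratio (penalty= spelling is deprecated in sklearn >=1.9)
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0,
        class_weight="balanced",
        solver="liblinear",
        max_iter=500,
        tol=1e-4,
        random_state=seed,
    )


def build_feature_matrix(
    cre_matrix: np.ndarray,
    cre_labels: list[str],
    state_flags: dict[str, list[bool | None]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-state (X, y) pairs from a reads x CREs matrix and flag columns.

    Rows with an undefined (None) flag are dropped for that state; states
    with fewer than two observed classes are skipped with a log message.
    """
    X_all = np.asarray(cre_matrix, dtype=float)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for state, flags in state_flags.items():
        keep = np.array([f is not None for f in flags])
        y = np.array([bool(f) for f, k in zip(flags, keep) if k], dtype=int)
        X = X_all[keep]
        if len(np.unique(y)) < 2:
            log.info("state %s: fewer than two classes observed; skipped", state)
            continue
        out[state] = (X, y)
    return out


def make_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignments, lowering K to the largest feasible value."""
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to stratify")
    counts = np.bincount(y)
    k_eff = min(k, int(counts[counts > 0].min()))
    if k_eff < 2:
        raise ValueError("smallest class has <2 members; cannot cross-validate")
    if k_eff < k:
        log.info("lowering K from %d to %d (class sizes)", k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


def oof_scores(
    X: np.ndarray, y: np.ndarray, folds, seed: int = 0
) -> tuple[float, float]:
    """Pooled out-of-fold (AUC, average precision).

    An empty feature matrix scores the conventional 0.5 AUC (AP = base rate).
    """
    if X.shape[1] == 0:
        return EMPTY_MODEL_AUC, float(y.mean())
    probs = np.empty(len(y))
    for tr, te in folds:
        est = _make_estimator(seed)
        est.fit(X[tr], y[tr])
        probs[te] = est.predict_proba(X[te])[:, 1]
    return float(roc_auc_score(y, probs)), float(average_precision_score(y, probs))


def fit_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    n_permutations: int = 50,
    seed: int = 0,
    gene_id: str = "",
    state: str = "",
    feature_names: list[str] | None = None,
    compute_dropout: bool = True,
) -> tuple[RegressionModel, ModelEvaluation]:
    """Full evaluation for one gene x state.

    Folds are drawn once and reused for the full model, single-feature
    models and all dropout/subset refits, so dAUC isolates feature removal.
    The permutation null re-stratifies per shuffle (stratification depends
    on the labels).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    folds = make_folds(y, k, seed)

    auc, ap = oof_scores(X, y, folds, seed)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        y_perm = rng.permutation(y)
        perm_folds = make_folds(y_perm, k, seed + 1 + p)
        null[p], _ = oof_scores(X, y_perm, perm_folds, seed)

    single = {}
    for j, name in enumerate(names):
        single[name], _ = oof_scores(X[:, [j]], y, folds, seed)

    dropout = {}
    if compute_dropout:
        dropout = dropout_analysis(X, y, folds, names, auc, seed)

    est = _make_estimator(seed)
    est.fit(X, y)
    n_iter = int(np.max(est.n_iter_))
    converged = n_iter < est.max_iter
    if not converged:
        log.warning("%s/%s: solver hit max_iter=%d", gene_id, state, est.max_iter)

    model = RegressionModel(
        gene_id, state, float(est.intercept_[0]), est.coef_.ravel().copy(),
        list(names), converged,
    )
    evaluation = ModelEvaluation(
        auc=auc,
        average_precision=ap,
        null_aucs=null,
        delta_auc=float(auc - null.mean()),
        single_feature_aucs=single,
        dropout_delta_auc=dropout,
        k_used=len(folds),
        seed=seed,
    )
    return model, evaluation


def dropout_analysis(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    feature_names: list[str],
    auc_full: float,
    seed: int = 0,
) -> dict[str, float]:
    """dAUC_j = AUC_full - AUC without feature j, identical folds."""
    out = {}
    for j, name in enumerate(feature_names):
        keep = [c for c in range(X.shape[1]) if c != j]
        auc_j, _ = oof_scores(X[:, keep], y, folds, seed)
        out[name] = float(auc_full - auc_j)
    return out


def synergy(
    X: np.ndarray,
    y: np.ndarray,
    subset: tuple[int, ...],
    folds,
    feature_names: list[str],
    auc_full: float,
    singleton_dropouts: dict[str, float],
    seed: int = 0,
    n_permutations: int = 0,
    k: int = 5,
) -> SynergyResult:
    """Synergy(S) = sum_{i in S} dAUC_i - dAUC_S (same folds throughout)."""
    if any(j >= X.shape[1] or j < 0 for j in subset):
        raise ValueError("subset indexes a feature outside the matrix")
    names = tuple(feature_names[j] for j in subset)
    missing = [n for n in names if n not in singleton_dropouts]
    if missing:
        raise ValueError(f"singleton dropouts missing for {missing}")
    keep = [c for c in range(X.shape[1]) if c not in set(subset)]
    auc_s, _ = oof_scores(X[:, keep], y, folds, seed)
    d_s = float(auc_full - auc_s)
    s_sum = float(sum(singleton_dropouts[n] for n in names))
    null = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for p in range(n_permutations):
            y_perm = rng.permutation(y)
            perm_folds = make_folds(y_perm, k, seed + 1 + p)
            full_p, _ = oof_scores(X, y_perm, perm_folds, seed)
            singles = {
                feature_names[j]: full_p
                - oof_scores(np.delete(X, j, axis=1), y_perm, perm_folds, seed)[0]
                for j in subset
            }
            sub_p, _ = oof_scores(X[:, keep], y_perm, perm_folds, seed)
            null[p] = sum(singles.values()) - (full_p - sub_p)
    return SynergyResult(names, len(subset), s_sum - d_s, d_s, s_sum, null)


def synergy_scan(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    feature_names: list[str],
    auc_full: float,
    singleton_dropouts: dict[str, float],
    ks: tuple[int, ...] = (2,),
    seed: int = 0,
) -> list[SynergyResult]:
    """All subsets of the requested sizes (k in 2..4)."""
    out = []
    for k in ks:
        if k not in (2, 3, 4):
            raise ValueError("subset sizes are limited to 2-4")
        for subset in combinations(range(X.shape[1]), k):
            out.append(
                synergy(
                    X, y, subset, folds, feature_names, auc_full,
                    singleton_dropouts, seed,
                )
            )
    return out
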