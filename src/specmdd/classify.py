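"""MDD-vs-HC classification: logistic regression under leave-one-subject-out
cross-validation, scored by AUC with stratified-bootstrap confidence
intervals, over the study's feature-combination menu.

The depressed group (MDD) is the positive class.  Features are z-scored
within each fold using training-fold statistics only, so the held-out
subject never leaks into standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import feature_key

POSITIVE = "MDD"

# The five single features selected in the electrode-level analysis.
SELECTED_FEATURES = {
    "frontal_alpha_periodic": feature_key("electrode", "periodic", "frontal", "alpha"),
    "frontal_alpha_psd": feature_key("electrode", "psd", "frontal", "alpha"),
    "parietal_theta_periodic": feature_key("electrode", "periodic", "parietal", "theta"),
    "parietal_theta_psd": feature_key("electrode", "psd", "parietal", "theta"),
    "parietal_aperiodic": feature_key("electrode", "aperiodic", "parietal"),
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named feature combination for one classifier."""

    name: str
    keys: tuple[str, ...]
    kind: str  # single | by_band | by_analysis_type | dual_component

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError("feature set must be nonempty")


@dataclass
class LogisticFit:
    coef: np.ndarray
    intercept: float
    converged: bool
    separation: bool
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ self.coef + self.intercept, -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class LosoResult:
    name: str
    subject_ids: list[str]
    labels: np.ndarray          # 1 = MDD
    probabilities: np.ndarray   # out-of-fold P(MDD)
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"name": self.name, "n_features": None, "auc": self.auc,
                "ci95": [self.ci_low, self.ci_high],
                "per_subject": [
                    {"subject_id": s, "label": int(l), "p_mdd": float(p)}
                    for s, l, p in zip(self.subject_ids, self.labels,
                                       self.probabilities)]}


def fit_logistic(X: np.ndarray, labels: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Unregularized maximum-likelihood logistic regression via IRLS.

    Convergence is declared when the log-likelihood change falls below
    ``tol``.  Perfect separation cannot converge (coefficients diverge); the
    iteration cap then stops the fit and ``separation`` is flagged, with the
    last iterate returned.  A rank-deficient weighted design falls back to a
    tiny ridge term, with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if np.all(y == y[0]):
        raise ValueError("labels are constant")
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    ll_old = -np.inf
    separation = converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        wx = Xd * w[:, None]
        A = Xd.T @ wx
        b = wx.T @ z
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient design; adding tiny ridge term")
            beta = np.linalg.solve(A + 1e-8 * np.eye(p + 1), b)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    # near-zero training error / diverging coefficients indicate separation
    # (the likelihood plateaus near 0, so IRLS may also "converge" there)
    eta = np.clip(Xd @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.all(np.abs(y - mu) < 1e-3) or np.max(np.abs(beta)) > 1e3:
        separation = True
    return LogisticFit(coef=beta[1:], intercept=float(beta[0]),
                       converged=converged, separation=separation, n_iter=it)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs where the
    positive outscores the negative, ties counted one half."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _binary_labels(groups) -> np.ndarray:
    return np.asarray([1 if g == POSITIVE else 0 for g in groups])


def loso_cv(table: pd.DataFrame, keys, name: str = "",
            max_iter: int = 100) -> LosoResult:
    """Leave-one-subject-out logistic-regression cross-validation.

    One fold per subject; within each fold the features are standardized
    with the training subjects' mean/SD only.  Pooled out-of-fold
    probabilities are scored with the Mann-Whitney AUC.

    Each fold's linear score is centered by the log-odds of its training
    base rate before pooling.  Leaving one subject out shifts the training
    class balance against the held-out label; without this centering an
    uninformative feature yields pooled scores that anti-correlate with the
    labels (null AUC far below 1/2) purely through that artifact.
    """
    keys = list(keys)
    missing = [k for k in keys if k not in table.columns]
    if missing:
        raise KeyError(f"unknown feature keys: {missing}")
    sub = table.dropna(subset=keys).reset_index(drop=True)
    y = _binary_labels(sub["group"])
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    X = sub[keys].to_numpy(dtype=float)
    n = len(sub)
    probs = np.empty(n)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold lost one class entirely")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        fit = fit_logistic((X[train] - mu) / sd, y[train], max_iter=max_iter)
        eta = float(((X[i] - mu) / sd) @ fit.coef + fit.intercept)
        pi = y[train].mean()
        eta -= np.log(pi / (1.0 - pi))  # training base-rate centering
        probs[i] = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    return LosoResult(name=name or "+".join(keys),
                      subject_ids=list(sub["subject_id"]) if "subject_id" in sub
                      else [str(i) for i in range(n)],
                      labels=y, probabilities=probs, auc=auc(probs, y))


def bootstrap_auc_ci(result: LosoResult, n_boot: int = 1000,
                     seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI for the AUC by resampling subjects with
    replacement, stratified by class so every resample contains both."""
    rng = np.random.default_rng(seed)
    pos_idx = np.where(result.labels == 1)[0]
    neg_idx = np.where(result.labels == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = auc(result.probabilities[idx], result.labels[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    result.ci_low, result.ci_high = float(lo), float(hi)
    result.n_bootstrap, result.seed = n_boot, seed
    return float(lo), float(hi)


def enumerate_feature_sets(selected: dict[str, str] | None = None) -> list[FeatureSetSpec]:
    """The classification menu over the five selected features.

    5 singles, 2 within-band pairs (periodic + PSD inside alpha, inside
    theta), 2 within-analysis-type pairs (theta + alpha inside periodic,
    inside PSD) and the 3-feature dual-component set (periodic parietal
    theta + periodic frontal alpha + parietal aperiodic): 10 sets in all.
    """
    sel = dict(SELECTED_FEATURES if selected is None else selected)
    required = set(SELECTED_FEATURES)
    unknown = set(sel) - required
    if unknown or set(sel) != required:
        raise KeyError(f"selected features must be exactly {sorted(required)}")
    f = sel
    sets = [FeatureSetSpec(name, (f[name],), "single") for name in (
        "frontal_alpha_periodic", "frontal_alpha_psd",
        "parietal_theta_periodic", "parietal_theta_psd", "parietal_aperiodic")]
    sets += [
        FeatureSetSpec("alpha_periodic+psd",
                       (f["frontal_alpha_periodic"], f["frontal_alpha_psd"]),
                       "by_band"),
        FeatureSetSpec("theta_periodic+psd",
                       (f["parietal_theta_periodic"], f["parietal_theta_psd"]),
                       "by_band"),
        FeatureSetSpec("periodic_theta+alpha",
                       (f["parietal_theta_periodic"], f["frontal_alpha_periodic"]),
                       "by_analysis_type"),
        FeatureSetSpec("psd_theta+alpha",
                       (f["parietal_theta_psd"], f["frontal_alpha_psd"]),
                       "by_analysis_type"),
        FeatureSetSpec("periodic+aperiodic",
                       (f["parietal_theta_periodic"], f["frontal_alpha_periodic"],
                        f["parietal_aperiodic"]),
                       "dual_component"),
    ]
    return sets


def run_menu(table: pd.DataFrame, sets: list[FeatureSetSpec] | None = None,
             n_boot: int = 1000, seed: int = 0) -> list[LosoResult]:
    """LOSO-evaluate every feature set in the menu, with bootstrap CIs.

    Each set's bootstrap stream is derived deterministically from ``seed``.
    """
    sets = sets or enumerate_feature_sets()
    out = []
    for k, spec in enumerate(sets):
        res = loso_cv(table, spec.keys, name=spec.name)
        bootstrap_auc_ci(res, n_boot=n_boot, seed=int(seed) + 1000 * k)
        out.append(res)
    return out
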