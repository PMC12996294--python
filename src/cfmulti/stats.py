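"""Statistical layer: group tests, logistic models, ROC/AUC and DeLong.

Rank tests, exact Fisher tests and correlations wrap scipy; the logistic
GLM is fit by iteratively reweighted least squares in-package (the fit must
expose deviances for likelihood-ratio testing and flag-and-cap separation),
and AUC pair counting, DeLong's covariance estimator for paired AUC
comparison and the stratified bootstrap are implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


@dataclass
class GroupTestResult:
    statistic: float  # Kruskal-Wallis H (tie-corrected)
    p: float
    pairwise: list[dict]  # pair, z, p, p_adj


def kruskal_dunn(values: np.ndarray, groups: np.ndarray) -> GroupTestResult:
    """Kruskal-Wallis omnibus test with Dunn's post hoc pairwise z tests.

    Dunn's z uses mean ranks from the pooled ranking with tie correction;
    pairwise p-values are BH-adjusted over the family of all unordered
    group pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in dict.fromkeys(groups)]  # keep first-seen order
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    stat, p = sps.kruskal(*samples)

    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}

    pairwise = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        pairwise.append({"pair": (a, b), "z": float(z),
                         "p": float(2 * sps.norm.sf(abs(z)))})
    adj = bh_adjust([d["p"] for d in pairwise])
    for d, pa in zip(pairwise, adj):
        d["p_adj"] = float(pa)
    return GroupTestResult(statistic=float(stat), p=float(p), pairwise=pairwise)


def spearman(x, y) -> tuple[float, float]:
    r = sps.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    r = sps.fisher_exact(np.asarray(table))
    return float(r[0]), float(r[1])


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    r = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# logistic GLM (IRLS)


@dataclass
class ModelFit:
    """A fitted binary logistic model on z-scored predictors."""

    label: str
    names: list[str]
    coef: np.ndarray  # intercept first, on the z-scored predictor scale
    deviance: float
    fitted: np.ndarray
    n_obs: int
    n_pos: int
    converged: bool
    separation: bool
    predictor_means: np.ndarray = field(default_factory=lambda: np.array([]))
    predictor_sds: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: float | None = None
    deviance_path: np.ndarray | None = None  # per-IRLS-iteration deviances

    @property
    def n_params(self) -> int:
        return self.coef.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.predictor_means) / self.predictor_sds
        eta = self.coef[0] + Z @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray | None,
    names: list[str] | None = None,
    label: str = "model",
    max_iter: int = 100,
    tol: float = 1e-8,
    coef_cap: float = 15.0,
) -> ModelFit:
    """Binary logistic regression via iteratively reweighted least squares.

    Continuous predictors are z-scored before fitting. Convergence is
    declared when the largest coefficient update falls below ``tol``.
    (Quasi-)complete separation is detected via runaway coefficients or
    degenerate fitted probabilities; the fit is flagged and coefficients
    capped at ``coef_cap`` rather than failing.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n = y.size
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        Z = np.empty((n, 0))
        means = np.array([])
        sds = np.array([])
        names = []
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        if np.any(sds == 0):
            bad = [(names or [f"x{i}" for i in range(X.shape[1])])[i]
                   for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant predictor column(s) after z-scoring: {bad}")
        Z = (X - means) / sds
        names = names or [f"x{i}" for i in range(X.shape[1])]

    D = np.column_stack([np.ones(n), Z])

    eps = 1e-12

    def _mu(b):
        return 1.0 / (1.0 + np.exp(-np.clip(D @ b, -30, 30)))

    def _deviance(b):
        mu = _mu(b)
        return -2.0 * float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))

    # damped IRLS: full Newton step, halved until the deviance does not
    # increase; coefficients projected onto the [-cap, cap] box (separation
    # drives them to the boundary, flagged rather than failing)
    beta = np.zeros(D.shape[1])
    dev = _deviance(beta)
    deviance_path = [dev]
    converged = False
    separation = False
    for _ in range(max_iter):
        mu = _mu(beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        WD = D * w[:, None]
        delta = np.linalg.solve(D.T @ WD, D.T @ (y - mu))
        accepted = False
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            if np.any(np.abs(cand) > coef_cap):
                separation = True
                cand = np.clip(cand, -coef_cap, coef_cap)
            dev_cand = _deviance(cand)
            if dev_cand <= dev + 1e-12:
                accepted = True
                break
            step /= 2
        if not accepted:
            converged = True
            break
        change = np.max(np.abs(cand - beta))
        beta, dev = cand, dev_cand
        deviance_path.append(dev)
        if change < tol:
            converged = True
            break

    fit = ModelFit(
        label=label, names=list(names), coef=beta, deviance=dev, fitted=_mu(beta),
        n_obs=n, n_pos=int(y.sum()), converged=converged, separation=separation,
        predictor_means=means, predictor_sds=sds,
    )
    fit.deviance_path = np.asarray(deviance_path)
    return fit


def likelihood_ratio_test(fit_small: ModelFit, fit_large: ModelFit) -> tuple[float, int, float]:
    """chi2 = deviance_small - deviance_large; df = added parameter count."""
    if fit_small.n_obs != fit_large.n_obs:
        raise ValueError("nested models must share the same observations")
    df = fit_large.n_params - fit_small.n_params
    if df < 0:
        raise ValueError("fit_large must nest fit_small")
    chi2 = max(fit_small.deviance - fit_large.deviance, 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC by pair counting (ties count 0.5) plus the ROC curve points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both positive and negative labels")
    # pair counting via the rank-sum identity (equivalent, O(n log n))
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    order = np.argsort(-scores, kind="mergesort")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    curve = np.column_stack([
        np.r_[0, fps[distinct] / neg.size],  # FPR
        np.r_[0, tps[distinct] / pos.size],  # TPR
    ])
    return float(auc), curve


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.r_[pos, neg])
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # placement values of positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m  # placement values of negatives
    return float(auc), v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> dict:
    """DeLong's test for the difference of two correlated (paired) AUCs.

    Returns z, two-sided p, both AUCs, the difference and its 95% CI. When
    the variance of the difference degenerates (e.g. identical score
    vectors) the result is flagged and p set to 1.
    """
    labels = np.asarray(labels).astype(int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be paired and equal-length")
    auc_a, v10_a, v01_a = _delong_placements(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        return {"z": 0.0, "p": 1.0, "auc_a": auc_a, "auc_b": auc_b,
                "diff": diff, "ci": (diff, diff), "degenerate": True}
    se = float(np.sqrt(var_diff))
    z = diff / se
    p = float(2 * sps.norm.sf(abs(z)))
    ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
    return {"z": float(z), "p": p, "auc_a": auc_a, "auc_b": auc_b,
            "diff": float(diff), "ci": ci, "degenerate": False}


def delong_auc_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Single-model AUC with a DeLong variance confidence interval."""
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_placements(np.asarray(scores, dtype=float), labels)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    q = sps.norm.ppf(0.5 + level / 2)
    half = q * np.sqrt(max(var, 0.0))
    return auc, (max(auc - half, 0.0), min(auc + half, 1.0))


def bootstrap_auc(
    scores: np.ndarray, labels: np.ndarray, n_boot: int = 500, seed: int | np.random.Generator = 0
) -> dict:
    """Stratified bootstrap of the AUC (class counts preserved).

    Returns the mean bootstrap AUC and the 2.5/97.5 percentile interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        p = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        q = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.r_[p, q]
        aucs[i], _ = roc_auc(scores[idx], labels[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return {"mean_auc": float(aucs.mean()), "ci": (float(lo), float(hi)), "aucs": aucs}
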