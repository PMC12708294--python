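"""L1 predictor selection and model validation (ROC with DeLong CI, DCA).

The lasso path is solved by cyclic coordinate descent on internally
standardized columns with the objective ``(1/2n)·RSS + lambda·||beta||_1``
(gaussian) or the corresponding penalized deviance via IRLS (binomial),
over a 100-point log-spaced grid from ``lambda_max`` down to
``0.01·lambda_max``; the reported lambda minimises cross-validated deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "LassoFit",
    "RocResult",
    "DcaCurve",
    "soft_threshold",
    "lasso_fit",
    "select_predictors",
    "roc_analysis",
    "delong_ci",
    "decision_curve",
]


def soft_threshold(z: float, lam: float) -> float:
    """S(z, lam) = sign(z) * max(|z| - lam, 0)."""
    return float(np.sign(z) * max(abs(z) - lam, 0.0))


@dataclass
class LassoFit:
    variables: list[str]
    lambdas: np.ndarray
    coef_path: np.ndarray        # (n_lambda, p) on the standardized scale
    intercept_path: np.ndarray
    cv_deviance: np.ndarray
    chosen_index: int
    fold_ids: np.ndarray
    family: str
    seed: int
    dropped: list[str] = field(default_factory=list)

    @property
    def chosen_lambda(self) -> float:
        return float(self.lambdas[self.chosen_index])

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[self.chosen_index]

    @property
    def intercept(self) -> float:
        return float(self.intercept_path[self.chosen_index])


def _cd_weighted(x, z, w, lam, beta, tol=1e-10, max_iter=10_000):
    """Coordinate descent for (1/2n) sum w (z - b0 - X b)^2 + lam ||b||_1."""
    n, p = x.shape
    wsum = w.sum()
    xw = x * w[:, None]
    denom = (xw * x).sum(axis=0) / n
    eta = x @ beta
    b0 = float((w * (z - eta)).sum() / wsum)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if denom[j] <= 0:
                continue
            r_j = z - b0 - eta + x[:, j] * beta[j]
            rho = float(xw[:, j] @ r_j) / n
            new = soft_threshold(rho, lam) / denom[j]
            if new != beta[j]:
                eta += x[:, j] * (new - beta[j])
                delta = max(delta, abs(new - beta[j]))
                beta[j] = new
        new_b0 = float((w * (z - eta)).sum() / wsum)
        delta = max(delta, abs(new_b0 - b0))
        b0 = new_b0
        if delta < tol:
            break
    return beta, b0


def _gaussian_path(x, y, lambdas):
    n, p = x.shape
    w = np.ones(n)
    coefs = np.zeros((lambdas.size, p))
    icepts = np.zeros(lambdas.size)
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta, b0 = _cd_weighted(x, y, w, lam, beta.copy())
        coefs[i], icepts[i] = beta, b0
    return coefs, icepts


def _binomial_path(x, y, lambdas, irls_iter=30, irls_tol=1e-8):
    n, p = x.shape
    coefs = np.zeros((lambdas.size, p))
    icepts = np.zeros(lambdas.size)
    beta = np.zeros(p)
    pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    b0 = float(np.log(pbar / (1 - pbar)))
    for i, lam in enumerate(lambdas):
        beta, b0 = beta.copy(), b0
        for _ in range(irls_iter):
            eta = b0 + x @ beta
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-5, 1 - 1e-5)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            beta_new, b0_new = _cd_weighted(x, z, w, lam, beta.copy())
            shift = max(abs(b0_new - b0), float(np.max(np.abs(beta_new - beta)))
                        if beta.size else 0.0)
            beta, b0 = beta_new, b0_new
            if shift < irls_tol:
                break
        coefs[i], icepts[i] = beta, b0
    return coefs, icepts


def _deviance(x, y, coefs, icepts, family):
    eta = icepts[:, None] + coefs @ x.T  # (n_lambda, n)
    if family == "gaussian":
        return np.mean((y[None, :] - eta) ** 2, axis=1)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return -2.0 * np.mean(y[None, :] * np.log(mu) + (1 - y[None, :]) * np.log(1 - mu),
                          axis=1)


def _fold_ids(y, n_folds, family, rng):
    n = y.size
    ids = np.empty(n, dtype=int)
    if family == "binomial":
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            ids[idx] = np.arange(idx.size) % n_folds
    else:
        idx = rng.permutation(n)
        ids[idx] = np.arange(n) % n_folds
    return ids


def lasso_fit(X, y, family: str = "gaussian", cv_folds: int = 10, seed: int = 0,
              n_lambda: int = 100, lambda_min_ratio: float = 0.01,
              variables: list[str] | None = None) -> LassoFit:
    """Coordinate-descent lasso path with cross-validated lambda selection.

    ``X`` may be a pandas DataFrame (column names become variable names) or
    a 2-D array.  Columns are standardized internally; coefficients are
    reported on the standardized scale.  Constant columns are dropped with
    a warning; a constant outcome is an error.
    """
    if hasattr(X, "columns"):
        variables = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with y of length n")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if variables is None:
        variables = [f"x{j}" for j in range(X.shape[1])]
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    if y.std() == 0:
        raise ValueError("outcome is constant")
    if family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial outcome must be 0/1")
    n = y.size
    if n < cv_folds:
        raise ValueError("need n >= cv_folds")

    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [v for v, k in zip(variables, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}")
    variables = [v for v, k in zip(variables, keep) if k]
    X = X[:, keep]
    xs = (X - X.mean(axis=0)) / X.std(axis=0)

    if family == "gaussian":
        resid0 = y - y.mean()
    else:
        resid0 = y - y.mean()
    lam_max = float(np.max(np.abs(xs.T @ resid0)) / n)
    lam_max = max(lam_max, 1e-12)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    path_fn = _gaussian_path if family == "gaussian" else _binomial_path
    coefs, icepts = path_fn(xs, y, lambdas)

    rng = np.random.default_rng(seed)
    fold_ids = _fold_ids(y, cv_folds, family, rng)
    cv = np.zeros((cv_folds, lambdas.size))
    for k in range(cv_folds):
        tr, va = fold_ids != k, fold_ids == k
        # re-standardize inside the fold so the path sees unit-variance columns
        mu_k, sd_k = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd_k[sd_k == 0] = 1.0
        xk_tr = (X[tr] - mu_k) / sd_k
        xk_va = (X[va] - mu_k) / sd_k
        ck, ik = path_fn(xk_tr, y[tr], lambdas)
        cv[k] = _deviance(xk_va, y[va], ck, ik, family)
    cv_mean = cv.mean(axis=0)
    chosen = int(np.argmin(cv_mean))
    return LassoFit(variables, lambdas, coefs, icepts, cv_mean, chosen,
                    fold_ids, family, seed, dropped)


def select_predictors(fit: LassoFit) -> list[str]:
    """Nonzero-coefficient variables at the chosen lambda, ordered by
    |standardized coefficient| (largest first)."""
    beta = fit.coefficients
    idx = np.flatnonzero(beta != 0.0)
    order = idx[np.argsort(-np.abs(beta[idx]), kind="stable")]
    return [fit.variables[j] for j in order]


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_mann_whitney(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = _midrank(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC and its DeLong confidence interval.

    Uses the structural-component formulation: for each positive the
    fraction of negatives it outranks (ties half) and vice versa.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_analysis(scores, labels, threshold_rule: str = "youden") -> RocResult:
    """AUC with DeLong CI plus confusion metrics at the chosen threshold.

    ``youden`` maximises sensitivity + specificity - 1 over the empirical
    curve; ties resolve to the lower threshold.  Positives are predicted
    when ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    auc, lo, hi = delong_ci(scores, labels)
    if threshold_rule != "youden":
        raise ValueError("unknown threshold rule")
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    best_j, best_thr = -np.inf, None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = float((pred & (labels == 1)).sum()) / n_pos
        spec = float((~pred & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    pred = scores >= best_thr
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    return RocResult(
        auc=auc, ci_low=lo, ci_high=hi, threshold=best_thr,
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=(tp + tn) / (n_pos + n_neg),
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
    )


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    advantageous_ranges: list[tuple[float, float]]
    n_boot: int
    seed: int


def _net_benefit(scores, labels, thresholds):
    n = labels.size
    odds = thresholds / (1.0 - thresholds)
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & (labels == 1)[None, :]).sum(axis=1)
    fp = (pred & (labels == 0)[None, :]).sum(axis=1)
    return tp / n - fp / n * odds


def decision_curve(scores, labels, thresholds=None, n_boot: int = 2000,
                   seed: int = 0) -> DcaCurve:
    """Net-benefit curves for the model vs treat-all / treat-none.

    ``NB(p_t) = TP/n - FP/n * p_t/(1-p_t)``; treat-all uses the prevalence.
    A percentile bootstrap over ``n_boot`` resamples gives the band, and
    threshold ranges where the model strictly beats both references are
    reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.99, 100)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds >= 1.0):
        raise ValueError("thresholds must be < 1 (odds undefined at 1)")
    if np.any(thresholds < 0.0):
        raise ValueError("thresholds must be >= 0")

    n = labels.size
    prev = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = _net_benefit(scores, labels, thresholds)
    nb_all = prev - (1.0 - prev) * odds
    nb_none = np.zeros_like(thresholds)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, thresholds.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = _net_benefit(scores[idx], labels[idx], thresholds)
    band_low = np.percentile(boots, 2.5, axis=0)
    band_high = np.percentile(boots, 97.5, axis=0)

    better = (nb_model > nb_all) & (nb_model > 0)
    ranges: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(better):
        if flag and start is None:
            start = thresholds[i]
        elif not flag and start is not None:
            ranges.append((float(start), float(thresholds[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(start), float(thresholds[-1])))

    return DcaCurve(thresholds, nb_model, nb_all, nb_none,
                    band_low, band_high, ranges, n_boot, seed)
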