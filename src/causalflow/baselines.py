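"""Information-based directed-connectivity baselines.

Five estimators of source -> target influence, all scored so that a positive
value means the source's past improves prediction of the target beyond the
target's own past:

* GC  — univariate Granger causality, ln(RSS_restricted / RSS_full) from
  least-squares autoregressions;
* MGC — multivariate (conditional) GC: the source's past is added to a model
  already containing every other unit's past;
* EGC — extended GC: the same error-ratio improvement evaluated by local
  linear fits inside phase-space neighborhoods of the joint delay embedding;
* NGC — nonlinear GC with radial-basis-function autoregression (k-means
  centers, width = median inter-center distance);
* TE  — transfer entropy in bits, plug-in estimate over equal-occupancy bins
  minus a time-shuffled-source bias term.

Matrices follow the package-wide rows=targets / columns=sources orientation.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .datatypes import BaselineMatrix, EnsembleTimeSeries

__all__ = [
    "gc_univariate",
    "gc_multivariate",
    "gc_extended",
    "gc_nonlinear_rbf",
    "transfer_entropy",
    "select_order_bic",
    "compute_baseline_matrix",
]

_RIDGE = 1e-8


def _lags(x: np.ndarray, order: int) -> np.ndarray:
    """Design block of lagged values: row t (for target index t+order) is
    [x(t+order-1), ..., x(t+order-order)]."""
    T = len(x)
    return np.column_stack([x[order - k : T - k] for k in range(1, order + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of least squares y ~ X (intercept included);
    falls back to a small ridge penalty on rank deficiency, with a warning."""
    X1 = np.column_stack([np.ones(len(X)), X])
    coef, rss, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    if rank < X1.shape[1]:
        warnings.warn("rank-deficient design; using ridge fallback")
        A = X1.T @ X1 + _RIDGE * np.eye(X1.shape[1])
        coef = np.linalg.solve(A, X1.T @ y)
    resid = y - X1 @ coef
    return float(resid @ resid), X1.shape[1]


def select_order_bic(x: np.ndarray, max_order: int = 10) -> int:
    """Autoregressive order by BIC of the univariate AR fit."""
    x = np.asarray(x, float)
    best, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        y = x[p:]
        rss, k = _ols_rss(_lags(x, p), y)
        n = len(y)
        bic = n * np.log(max(rss / n, 1e-300)) + k * np.log(n)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def gc_univariate(
    x_target: np.ndarray, x_source: np.ndarray, order: int | None = None
) -> tuple[float, float]:
    """Univariate Granger causality source -> target.

    Returns ``(score, p)``: the log error ratio ln(RSS_restricted/RSS_full)
    and the F-test p-value for the source-lag coefficients.
    """
    x_target = np.asarray(x_target, float)
    x_source = np.asarray(x_source, float)
    if order is None:
        order = select_order_bic(x_target)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(x_target) < 10 * order:
        raise ValueError("series too short for the requested order")
    y = x_target[order:]
    Xr = _lags(x_target, order)
    Xf = np.column_stack([Xr, _lags(x_source, order)])
    rss_r, _ = _ols_rss(Xr, y)
    rss_f, k_f = _ols_rss(Xf, y)
    rss_f = max(rss_f, 1e-300)
    score = float(np.log(max(rss_r, 1e-300) / rss_f))
    n = len(y)
    df2 = n - k_f
    F = ((rss_r - rss_f) / order) / (rss_f / df2) if df2 > 0 else np.nan
    p = float(stats.f.sf(max(F, 0.0), order, df2)) if np.isfinite(F) else np.nan
    return score, p


def gc_multivariate(ensemble: EnsembleTimeSeries, order: int | None = None) -> BaselineMatrix:
    """Conditional GC: source past added to a model already containing all
    other units' pasts."""
    V = ensemble.values
    n, T = V.shape
    if order is None:
        order = max(select_order_bic(V[i]) for i in range(n))
    if n * order >= T:
        raise ValueError("insufficient samples for conditional model")
    blocks = [_lags(V[j], order) for j in range(n)]
    scores = np.full((n, n), np.nan)
    for i in range(n):
        y = V[i][order:]
        X_full = np.column_stack(blocks)
        rss_f, _ = _ols_rss(X_full, y)
        rss_f = max(rss_f, 1e-300)
        for j in range(n):
            if j == i:
                continue
            X_r = np.column_stack([blocks[m] for m in range(n) if m != j])
            rss_r, _ = _ols_rss(X_r, y)
            scores[i, j] = np.log(max(rss_r, 1e-300) / rss_f)
    return BaselineMatrix(
        values=scores, unit_ids=list(ensemble.unit_ids), method="MGC", meta={"order": order}
    )


def gc_extended(
    x_target: np.ndarray,
    x_source: np.ndarray,
    d: int = 3,
    tau: int = 1,
    neighborhood_frac: float = 0.1,
    n_anchors: int = 30,
    seed: int = 0,
) -> float:
    """Extended (locally linear) GC in delay space.

    Around each anchor state of the joint (target, source) embedding, the
    target's next value is fit linearly from target lags (restricted) vs
    target + source lags (full) using only the neighborhood's states; the
    score is the mean local ln error-ratio improvement.
    """
    x_target = np.asarray(x_target, float)
    x_source = np.asarray(x_source, float)
    span = (d - 1) * tau + 1
    T = len(x_target)
    t_idx = np.arange(span - 1, T - 1)  # predict value at t+1
    tgt_lags = np.column_stack([x_target[t_idx - k * tau] for k in range(d)])
    src_lags = np.column_stack([x_source[t_idx - k * tau] for k in range(d)])
    joint = np.column_stack([tgt_lags, src_lags])
    y = x_target[t_idx + 1]
    n_states = len(t_idx)
    k_nb = max(int(neighborhood_frac * n_states), 3 * (2 * d + 1))
    rng = np.random.default_rng(seed)
    anchors = rng.choice(n_states, size=min(n_anchors, n_states), replace=False)
    tree = cKDTree(joint)
    ratios = []
    for a in anchors:
        _, nb = tree.query(joint[a], k=min(k_nb, n_states))
        nb = np.atleast_1d(nb)
        rss_r, _ = _ols_rss(tgt_lags[nb], y[nb])
        rss_f, _ = _ols_rss(joint[nb], y[nb])
        ratios.append(np.log(max(rss_r, 1e-300) / max(rss_f, 1e-300)))
    return float(np.mean(ratios))


def _rbf_features(X: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * width**2))


def gc_nonlinear_rbf(
    x_target: np.ndarray,
    x_source: np.ndarray,
    n_centers: int = 20,
    width: float | None = None,
    order: int = 2,
    seed: int = 0,
) -> float:
    """Nonlinear GC with RBF autoregression.

    Lag vectors are mapped through radial basis functions (centers by k-means
    on the lag vectors, width = median inter-center distance unless given);
    the score is ln(RSS_restricted / RSS_full) of the linear fit in feature
    space.  The full model's features extend the restricted model's (target
    RBFs plus source RBFs), so the score is nonnegative up to estimator
    noise.
    """
    x_target = np.asarray(x_target, float)
    x_source = np.asarray(x_source, float)
    y = x_target[order:]

    def features(X: np.ndarray) -> np.ndarray:
        km = KMeans(n_clusters=min(n_centers, len(X)), n_init=3, random_state=seed).fit(X)
        C = km.cluster_centers_
        if width is None:
            dc = np.sqrt(((C[:, None] - C[None, :]) ** 2).sum(-1))
            w = float(np.median(dc[np.triu_indices(len(C), 1)])) if len(C) > 1 else 1.0
            w = max(w, 1e-6)
        else:
            w = width
        return _rbf_features(X, C, w)

    phi_tgt = features(_lags(x_target, order))
    phi_src = features(_lags(x_source, order))
    rss_r, _ = _ols_rss(phi_tgt, y)
    rss_f, _ = _ols_rss(np.column_stack([phi_tgt, phi_src]), y)
    return float(np.log(max(rss_r, 1e-300) / max(rss_f, 1e-300)))


def _equal_occupancy_digitize(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(x, qs)


def transfer_entropy(
    x_target: np.ndarray,
    x_source: np.ndarray,
    k_history: int = 1,
    n_bins: int = 4,
    n_perm: int = 20,
    seed: int = 0,
) -> float:
    """Bias-corrected transfer entropy source -> target, in bits.

    Plug-in estimate of
    TE = sum p(y+, y^k, x^k) log2[ p(y+|y^k, x^k) / p(y+|y^k) ]
    over equal-occupancy bins, minus the mean TE of ``n_perm`` circularly
    time-shifted source surrogates.  Set ``n_perm=0`` for the raw (nonnegative)
    plug-in value.
    """
    x_target = np.asarray(x_target, float)
    x_source = np.asarray(x_source, float)
    T = len(x_target)
    if n_bins ** (2 * k_history + 1) > T / 5:
        raise ValueError(
            f"undersampled joint histogram: n_bins^(2k+1) = {n_bins ** (2 * k_history + 1)} > T/5"
        )
    yb = _equal_occupancy_digitize(x_target, n_bins)
    xb = _equal_occupancy_digitize(x_source, n_bins)

    def plugin(xb_shifted: np.ndarray) -> float:
        k = k_history
        idx = np.arange(k, T - 1)
        # integer codes for y_{t+1}, y_t^k, x_t^k
        code_yp = yb[idx + 1]
        code_yh = np.zeros(len(idx), dtype=np.int64)
        code_xh = np.zeros(len(idx), dtype=np.int64)
        for m in range(k):
            code_yh = code_yh * n_bins + yb[idx - m]
            code_xh = code_xh * n_bins + xb_shifted[idx - m]
        nyh = n_bins**k
        joint = code_yp * (nyh * nyh) + code_yh * nyh + code_xh
        cnt = np.bincount(joint, minlength=n_bins * nyh * nyh).astype(float)
        cnt = cnt.reshape(n_bins, nyh, nyh)
        N = cnt.sum()
        p_yyx = cnt / N
        p_yx = cnt.sum(axis=0)  # (y^k, x^k)
        p_yy = cnt.sum(axis=2)  # (y+, y^k)
        p_y = cnt.sum(axis=(0, 2))  # (y^k,)
        with np.errstate(divide="ignore", invalid="ignore"):
            num = cnt * p_y[None, :, None]
            den = p_yx[None, :, :] * p_yy[:, :, None]
            logterm = np.where(cnt > 0, np.log2(np.where(cnt > 0, num, 1.0) / np.where(den > 0, den, 1.0)), 0.0)
        return float((p_yyx * logterm).sum())

    te = plugin(xb)
    if n_perm < 1:
        return te
    rng = np.random.default_rng(seed)
    null = [plugin(np.roll(xb, int(rng.integers(1, T - 1)))) for _ in range(n_perm)]
    return te - float(np.mean(null))


def compute_baseline_matrix(
    ensemble: EnsembleTimeSeries,
    method: str,
    order: int | None = None,
    seed: int = 0,
    significance: bool = False,
    n_shifts: int = 99,
    alpha: float = 0.05,
    **kwargs,
) -> BaselineMatrix:
    """N x N directed scores for one estimator, CF-matrix orientation.

    ``method`` is one of ``gc``, ``mgc``, ``egc``, ``ngc``, ``te``.  Optional
    significance mirrors the CF testing burden with a circular time-shift
    surrogate null on the source series (one-sided add-one p < alpha).
    """
    method = method.lower()
    if method == "mgc":
        mat = gc_multivariate(ensemble, order=order)
    else:
        V = ensemble.values
        n = ensemble.n_units
        scores = np.full((n, n), np.nan)
        if method == "gc" and order is None:
            order = max(select_order_bic(V[i]) for i in range(n))

        def score_pair(tgt: np.ndarray, src: np.ndarray) -> float:
            if method == "gc":
                return gc_univariate(tgt, src, order=order)[0]
            if method == "egc":
                return gc_extended(tgt, src, seed=seed, **kwargs)
            if method == "ngc":
                return gc_nonlinear_rbf(tgt, src, seed=seed, **kwargs)
            if method == "te":
                return transfer_entropy(tgt, src, seed=seed, **kwargs)
            raise ValueError(f"unknown method {method!r}")

        for i in range(n):
            for j in range(n):
                if i != j:
                    scores[i, j] = score_pair(V[i], V[j])
        mat = BaselineMatrix(
            values=scores,
            unit_ids=list(ensemble.unit_ids),
            method=method.upper(),
            meta={"order": order, **kwargs},
        )
    if significance:
        mat = _shift_significance(ensemble, mat, method, order, n_shifts, alpha, seed, **kwargs)
    return mat


def _shift_significance(
    ensemble: EnsembleTimeSeries,
    mat: BaselineMatrix,
    method: str,
    order: int | None,
    n_shifts: int,
    alpha: float,
    seed: int,
    **kwargs,
) -> BaselineMatrix:
    rng = np.random.default_rng(seed)
    n = ensemble.n_units
    V = ensemble.values
    T = ensemble.n_samples
    pvals = np.full((n, n), np.nan)

    def score_fn(tgt, src) -> float:
        if method == "gc":
            return gc_univariate(tgt, src, order=order)[0]
        if method == "mgc":
            raise ValueError("shift significance for MGC is not supported; use per-pair methods")
        if method == "egc":
            return gc_extended(tgt, src, seed=seed, **kwargs)
        if method == "ngc":
            return gc_nonlinear_rbf(tgt, src, seed=seed, **kwargs)
        if method == "te":
            return transfer_entropy(tgt, src, seed=seed, **kwargs)
        raise ValueError(method)

    shifts = rng.integers(1, T - 1, size=n_shifts)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(mat.values[i, j]):
                continue
            null = np.array([score_fn(V[i], np.roll(V[j], int(s))) for s in shifts])
            pvals[i, j] = (1.0 + (null >= mat.values[i, j]).sum()) / (1.0 + n_shifts)
    finite = np.isfinite(pvals)
    sig = finite & (np.where(finite, pvals, 1.0) < alpha)
    meta = dict(mat.meta)
    meta.update({"n_shifts": n_shifts, "alpha": alpha, "seed": seed})
    return BaselineMatrix(
        values=mat.values, unit_ids=mat.unit_ids, sig_mask=sig, pvals=pvals, method=mat.method, meta=meta
    )
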