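"""Takens delay embedding, simplex-projection cross-mapping, and the
causal-flow (CF) matrix.

Cross-mapping asks how well the delay embedding of a *target* unit can
reconstruct a *source* unit's time series.  If the source causally drives the
target, the target's attractor contains a signature of the source and the
reconstruction succeeds; the converse does not hold.  Reconstruction skill is
the Pearson correlation ``rho`` between held-out source values and their
simplex-projection predictions, reported as the Fisher z transform
``z = arctanh(rho)``.  Cross-validation uses contiguous-block folds with a
Theiler exclusion window around the held-out block so temporal autocorrelation
cannot leak predictive skill.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import CFMatrix, DelayMatrix, EnsembleTimeSeries

__all__ = [
    "delay_embed",
    "fisher_z",
    "cross_map",
    "cross_map_many",
    "compute_cf_matrix",
    "select_hyperparameters",
    "SelectionResult",
]

_RHO_CLIP = 1.0 - 1e-12
_EPS = 1e-12


def delay_embed(series: np.ndarray, d: int, tau: int) -> DelayMatrix:
    """Delay-coordinate embedding X(t) = [x(t), x(t-tau), ..., x(t-(d-1)tau)].

    Rows are ordered by t, one per valid time index; a length-T series yields
    exactly ``T - (d-1)*tau`` rows.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if d < 1 or tau < 1:
        raise ValueError("d and tau must be >= 1")
    min_len = (d - 1) * tau + 2
    if len(series) < min_len:
        raise ValueError(f"series too short for d={d}, tau={tau}: need length >= {min_len}")
    t0 = (d - 1) * tau
    t_index = np.arange(t0, len(series))
    cols = [series[t_index - k * tau] for k in range(d)]
    return DelayMatrix(np.column_stack(cols), d=d, tau=tau, t_index=t_index)


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Fisher z transform arctanh(rho), with rho clipped away from +-1."""
    return np.arctanh(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))


def _block_folds(n_states: int, n_folds: int) -> list[np.ndarray]:
    """Contiguous blocks of state-row indices."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    edges = np.linspace(0, n_states, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


def _simplex_neighbors(emb: DelayMatrix, n_folds: int, k: int):
    """Per held-out state: times and weights of its k nearest library states.

    The library for each fold excludes the held-out block plus a Theiler
    margin of ``(d-1)*tau`` samples on either side.  Weights are the standard
    simplex-projection weights exp(-dist/dist_nearest), with exact-match
    handling when the nearest distance is zero.  Returns pooled arrays
    ``(test_times, neighbor_times, weights)`` usable against any source
    series.
    """
    states = emb.values
    if np.ptp(states, axis=0).max() < _EPS:
        raise ValueError("degenerate embedding: all states identical")
    folds = _block_folds(emb.n_states, n_folds)
    theiler = emb.theiler
    all_test, all_nb, all_w = [], [], []
    for test in folds:
        lo, hi = test[0], test[-1]
        lib = np.concatenate(
            [np.arange(0, max(lo - theiler, 0)), np.arange(min(hi + theiler + 1, emb.n_states), emb.n_states)]
        )
        if len(lib) < k:
            raise ValueError(f"library of {len(lib)} states smaller than k={k} neighbors")
        tree = cKDTree(states[lib])
        dists, nb = tree.query(states[test], k=k)
        dists = np.atleast_2d(dists)
        nb = np.atleast_2d(nb)
        d1 = dists[:, :1]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(d1 < _EPS, (dists < _EPS).astype(float), np.exp(-dists / np.maximum(d1, _EPS)))
        all_test.append(emb.t_index[test])
        all_nb.append(emb.t_index[lib[nb]])
        all_w.append(w)
    return np.concatenate(all_test), np.vstack(all_nb), np.vstack(all_w)


def _predict(nb_times: np.ndarray, w: np.ndarray, source: np.ndarray) -> np.ndarray:
    return (w * source[nb_times]).sum(axis=1) / w.sum(axis=1)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() < _EPS or b.std() < _EPS:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_map(
    reconstructor: DelayMatrix,
    source_series: np.ndarray,
    k_neighbors: int | None = None,
    n_folds: int = 5,
) -> tuple[float, float]:
    """Cross-map one source from the reconstructor's embedding.

    Returns ``(rho, z)``: the cross-validated Pearson correlation between
    held-out source values and their simplex predictions, and its Fisher z.
    """
    rho, z = cross_map_many(reconstructor, np.asarray(source_series, float)[None, :], k_neighbors, n_folds)
    return float(rho[0]), float(z[0])


def cross_map_many(
    reconstructor: DelayMatrix,
    sources: np.ndarray,
    k_neighbors: int | None = None,
    n_folds: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-map many source series at once from one reconstructor embedding.

    The neighbor search depends only on the reconstructor, so it is done once
    and reused for every source row; this is the workhorse behind both the CF
    matrix and surrogate re-testing.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.shape[1] < reconstructor.t_index[-1] + 1:
        raise ValueError("source series shorter than the reconstructor's time span")
    k = k_neighbors if k_neighbors is not None else reconstructor.d + 1
    if k < reconstructor.d + 1:
        raise ValueError("k_neighbors must be >= d+1 (simplex projection)")
    test_times, nb_times, w = _simplex_neighbors(reconstructor, n_folds, k)
    rhos = np.empty(sources.shape[0])
    for i, src in enumerate(sources):
        pred = _predict(nb_times, w, src)
        rhos[i] = _safe_pearson(pred, src[test_times])
    return rhos, fisher_z(rhos)


def compute_cf_matrix(
    ensemble: EnsembleTimeSeries,
    d: int = 6,
    tau: int = 4,
    k_neighbors: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CFMatrix:
    """Causal-flow matrix over all ordered unit pairs.

    ``F[i, j]`` reconstructs source ``j`` from target ``i``'s embedding
    (rows = targets / reconstructors, columns = sources).  Constant units are
    flagged missing (NaN row and column) with a warning rather than failing.
    """
    if ensemble.n_units < 2:
        raise ValueError("need at least 2 units")
    n = ensemble.n_units
    F = np.full((n, n), np.nan)
    const = ensemble.values.std(axis=1) < _EPS
    if const.any():
        warnings.warn(
            f"constant unit series flagged missing: {[ensemble.unit_ids[i] for i in np.nonzero(const)[0]]}"
        )
    for i in range(n):
        if const[i]:
            continue
        emb = delay_embed(ensemble.values[i], d, tau)
        src_idx = np.array([j for j in range(n) if j != i and not const[j]], dtype=int)
        if len(src_idx) == 0:
            continue
        _, z = cross_map_many(emb, ensemble.values[src_idx], k_neighbors, n_folds)
        F[i, src_idx] = z
    return CFMatrix(
        values=F,
        unit_ids=list(ensemble.unit_ids),
        meta={
            "d": d,
            "tau": tau,
            "k_neighbors": k_neighbors if k_neighbors is not None else d + 1,
            "n_folds": n_folds,
            "seed": seed,
        },
    )


class SelectionResult(NamedTuple):
    d: int
    tau: int
    plateau_found: bool
    scores: dict  # (d, tau) -> median cross-map z over probe pairs


def select_hyperparameters(
    ensemble: EnsembleTimeSeries,
    d_grid: Sequence[int] = range(2, 11),
    tau_grid: Sequence[int] = range(1, 9),
    plateau_tol: float = 0.02,
    n_probe_pairs: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Pick (d, tau) at the accuracy plateau.

    Cross-map accuracy grows with embedding dimension until the attractor is
    unfolded, then plateaus; we return the smallest d (then smallest tau,
    tie-break) whose median accuracy over a probe set of ordered pairs is
    within ``plateau_tol`` (z units) of the grid maximum.  If accuracy is
    still rising at the grid edge a warning is issued and the grid maximum is
    returned with ``plateau_found=False``.
    """
    d_grid = sorted(set(int(v) for v in d_grid))
    tau_grid = sorted(set(int(v) for v in tau_grid))
    if not d_grid or not tau_grid:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    n = ensemble.n_units
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    if len(pairs) > n_probe_pairs:
        pairs = [pairs[t] for t in rng.choice(len(pairs), size=n_probe_pairs, replace=False)]
    scores: dict[tuple[int, int], float] = {}
    for d in d_grid:
        for tau in tau_grid:
            zs = []
            for i, j in pairs:
                emb = delay_embed(ensemble.values[i], d, tau)
                _, z = cross_map(emb, ensemble.values[j], n_folds=n_folds)
                zs.append(z)
            scores[(d, tau)] = float(np.median(zs))
    best = max(scores.values())
    candidates = [dt for dt, s in scores.items() if s >= best - plateau_tol]
    d_sel, tau_sel = min(candidates, key=lambda dt: (dt[0], dt[1]))
    plateau_found = (d_sel < max(d_grid)) or (len(d_grid) == 1)
    if not plateau_found:
        warnings.warn(
            "no accuracy plateau within the d grid (still rising at the edge); returning grid maximum"
        )
    return SelectionResult(d_sel, tau_sel, plateau_found, scores)
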