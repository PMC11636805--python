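"""Twin surrogates and CF significance.

Twin surrogates re-thread an observed trajectory through phase space: states
whose recurrence neighborhoods (max-norm balls) coincide exactly are "twins"
and are dynamically interchangeable.  A surrogate walks the original
trajectory but, whenever its current state has twins, may jump to one of them
and continue from the twin's successor.  The surrogate preserves the marginal
distribution and attractor geometry of the original series while destroying
its causal alignment with any other series, which makes it the null model for
testing CF entries: an empirical cross-map skill is significant when it
exceeds the skill obtained after replacing the reconstructor series with its
surrogates.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control

from .datatypes import CFMatrix, DelayMatrix, EnsembleTimeSeries, SurrogateEnsemble, TwinSet
from .embedding import cross_map_many, delay_embed

__all__ = ["find_twins", "generate_surrogates", "cf_significance"]


def find_twins(
    embedding: DelayMatrix,
    radius_quantile: float = 0.1,
    theiler: int | None = None,
    tolerance: float = 0.02,
) -> TwinSet:
    """Partition embedded states into twin classes.

    The neighborhood radius is the given quantile of the off-diagonal
    pairwise max-norm distance distribution.  Two states are twins when they
    are mutual neighbors and their recurrence-matrix rows agree, the
    comparison excluding the tangential (Theiler) band of ``theiler`` samples
    around each of the two states — on finely sampled flows consecutive
    states are trivially recurrent, and without this correction the only
    "twins" are adjacent samples, which makes the surrogates pure time
    shifts.  ``tolerance`` allows a small fraction of the comparable columns
    to differ (exact comparison is the ``tolerance=0`` limit); twin classes
    are the connected components of the twin relation.  ``theiler`` defaults
    to the embedding's delay span ``(d-1)*tau``.
    """
    if embedding.n_states < 10:
        raise ValueError("need at least 10 embedded states")
    if not 0 < radius_quantile < 1:
        raise ValueError("radius_quantile must be in (0, 1)")
    if theiler is None:
        theiler = max(embedding.theiler, 1)
    n = embedding.n_states
    dists = pdist(embedding.values, metric="chebyshev")
    radius = float(np.quantile(dists, radius_quantile))
    R = squareform(dists) <= radius
    np.fill_diagonal(R, True)
    cols = np.arange(n)
    max_bad = int(np.floor(tolerance * n))
    pairs_i: list[int] = []
    pairs_j: list[int] = []
    for i in range(n):
        nbrs = np.nonzero(R[i])[0]
        nbrs = nbrs[(nbrs > i + theiler)]  # mutual neighbors, temporally distant
        if nbrs.size == 0:
            continue
        diff = R[nbrs] != R[i][None, :]
        near_i = np.abs(cols - i) <= theiler
        diff[:, near_i] = False
        for k, j in enumerate(nbrs):
            row = diff[k]
            bad = int(row.sum())
            if bad > max_bad:
                # re-count excluding j's own tangential band
                bad = int(row[np.abs(cols - j) > theiler].sum())
            if bad <= max_bad:
                pairs_i.append(i)
                pairs_j.append(int(j))
    adj = coo_matrix(
        (np.ones(len(pairs_i)), (pairs_i, pairs_j)), shape=(n, n)
    )
    _, class_of = connected_components(adj + adj.T, directed=False)
    classes = [np.nonzero(class_of == c)[0] for c in range(class_of.max() + 1)]
    if len(classes) == 1:
        raise ValueError("degenerate twin partition: all states are twins at this radius")
    return TwinSet(neighbor_radius=radius, class_of=np.asarray(class_of), classes=classes)


def _walk(
    n_states: int, length: int, class_of: np.ndarray, classes: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """One surrogate walk over state indices.

    At each step the walk stays on its trajectory's successor with the
    retention probability p = (n-1)/n (n = twin-class size) and otherwise
    jumps uniformly to one of the n-1 twins, continuing from that twin's
    successor.  Hitting the final recorded state jumps to a random twin of it,
    or restarts uniformly when it has none.
    """
    path = np.empty(length, dtype=np.int64)
    s = int(rng.integers(n_states))
    for t in range(length):
        path[t] = s
        members = classes[class_of[s]]
        n = len(members)
        if n > 1 and rng.random() < 1.0 / n:
            # jump uniformly to one of the twins (excluding the current state)
            others = members[members != s]
            s = int(others[rng.integers(len(others))])
        if s + 1 >= n_states:
            members = classes[class_of[s]]
            others = members[members != s]
            if len(others):
                s = int(others[rng.integers(len(others))]) + 1
                if s >= n_states:  # twin was itself the last state
                    s = int(rng.integers(n_states))
            else:
                s = int(rng.integers(n_states))
        else:
            s = s + 1
    return path


def generate_surrogates(
    series: np.ndarray,
    embedding: DelayMatrix,
    twinset: TwinSet,
    n_surrogates: int = 99,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Generate twin surrogates of one scalar series.

    Each surrogate has the original length and takes values only from the
    original series (trajectory re-threading).  Per-surrogate seeds are
    spawned deterministically from ``seed``.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if twinset.n_states != embedding.n_states:
        raise ValueError("twinset was not built from this embedding")
    series = np.asarray(series, dtype=float)
    length = len(series)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_surrogates)]
    out = np.empty((n_surrogates, length))
    for i, s_i in enumerate(child_seeds):
        rng = np.random.default_rng(s_i)
        path = _walk(embedding.n_states, length, twinset.class_of, twinset.classes, rng)
        out[i] = series[embedding.t_index[path]]
    return SurrogateEnsemble(
        series=out,
        seeds=child_seeds,
        params={"radius": twinset.neighbor_radius, "n_surrogates": n_surrogates, "seed": seed},
    )


def cf_significance(
    ensemble: EnsembleTimeSeries,
    cf: CFMatrix,
    n_surrogates: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
    radius_quantile: float = 0.1,
    fdr: bool = False,
) -> CFMatrix:
    """Fill the CF significance mask by twin-surrogate testing.

    For each ordered pair (target i, source j) the cross-map skill is
    recomputed with target i's series replaced by each of its twin surrogates
    (same d, tau, folds as the empirical CF); the one-sided add-one empirical
    p-value is ``p = (1 + #{F_surr >= F_emp}) / (1 + n_surrogates)`` and
    ``sig = p < alpha`` (optionally Benjamini-Hochberg corrected across pairs
    with ``fdr=True``).
    """
    if 1.0 / (1 + n_surrogates) > alpha:
        raise ValueError(
            f"n_surrogates={n_surrogates} too small for alpha={alpha}: minimum attainable "
            f"p-value is {1.0 / (1 + n_surrogates):.4g}"
        )
    d, tau = cf.meta["d"], cf.meta["tau"]
    n_folds = cf.meta.get("n_folds", 5)
    k = cf.meta.get("k_neighbors")
    n = cf.n_units
    pvals = np.full((n, n), np.nan)
    ss = np.random.SeedSequence(seed)
    unit_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    for i in range(n):
        src_idx = np.array([j for j in range(n) if j != i and np.isfinite(cf.values[i, j])], dtype=int)
        if len(src_idx) == 0:
            continue
        emb = delay_embed(ensemble.values[i], d, tau)
        twins = find_twins(emb, radius_quantile)
        surr = generate_surrogates(ensemble.values[i], emb, twins, n_surrogates, seed=unit_seeds[i])
        # surrogate skill: re-embed each surrogate of the reconstructor,
        # cross-map every source from it
        exceed = np.zeros(len(src_idx))
        for s_series in surr.series:
            s_emb = delay_embed(s_series, d, tau)
            _, z_surr = cross_map_many(s_emb, ensemble.values[src_idx], k, n_folds)
            exceed += z_surr >= cf.values[i, src_idx]
        pvals[i, src_idx] = (1.0 + exceed) / (1.0 + n_surrogates)
    finite = np.isfinite(pvals)
    if fdr and finite.any():
        adj = np.full_like(pvals, np.nan)
        adj[finite] = false_discovery_control(pvals[finite], method="bh")
        sig = finite & (np.where(finite, adj, 1.0) < alpha)
    else:
        sig = finite & (np.where(finite, pvals, 1.0) < alpha)
    meta = dict(cf.meta)
    meta.update({"n_surrogates": n_surrogates, "alpha": alpha, "surrogate_seed": seed, "fdr": fdr})
    return CFMatrix(values=cf.values.copy(), unit_ids=list(cf.unit_ids), sig_mask=sig, pvals=pvals, meta=meta)
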