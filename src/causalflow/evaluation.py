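"""Does resting-state connectivity predict perturbation effects?

This module hosts the comparison machinery: Gini coefficients of
connectivity/perturbation vectors (hierarchy), spatial footprints and
distance residualization on an array geometry, the CF-vs-IC prediction tests
(Pearson correlation over ordered pairs, per-source regressions, significant
vs nonsignificant group comparison), and a PCA of CF column vectors that
exposes the driver/driven subnetwork hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import ArrayGeometry, CFMatrix, ICMatrix, _DirectedMatrix

__all__ = [
    "gini",
    "default_geometry",
    "spatial_footprint",
    "residualize_distance",
    "prediction_tests",
    "cf_hierarchy_pca",
    "PredictionReport",
]


def gini(v: np.ndarray) -> float:
    """Population Gini coefficient G = sum_{a,b} |v_a - v_b| / (2 m^2 mean).

    0 for a constant vector, 0.5 for exponentially distributed samples.
    Negative entries (e.g. negative Fisher-z CF values) are floored at zero
    with a warning; an all-zero vector has no defined Gini.
    """
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("undefined Gini: no finite entries")
    if np.any(v < 0):
        warnings.warn("negative entries floored at 0 for Gini")
        v = np.maximum(v, 0.0)
    if v.mean() == 0:
        raise ValueError("undefined Gini: all-zero vector")
    m = v.size
    vs = np.sort(v)
    # sorted identity: sum_{a,b}|v_a - v_b| = 2 * sum_i (2i - m + 1) v_(i)
    total = 2.0 * np.sum((2 * np.arange(m) - m + 1) * vs)
    return float(total / (2.0 * m * m * vs.mean()))


def default_geometry(unit_ids: list[str], pitch: float = 1.0) -> ArrayGeometry:
    """Synthetic array layout: units on a 10x10 grid minus the four corners
    (the 96-channel footprint), row-major, truncated to the unit count."""
    coords = []
    for r in range(10):
        for c in range(10):
            if (r, c) in ((0, 0), (0, 9), (9, 0), (9, 9)):
                continue
            coords.append((float(c), float(r)))
    if len(unit_ids) > len(coords):
        raise ValueError(f"default geometry holds at most {len(coords)} units")
    return ArrayGeometry(unit_ids=list(unit_ids), coordinates=np.array(coords[: len(unit_ids)]), pitch=pitch)


def _pair_arrays(matrix: _DirectedMatrix, geom: ArrayGeometry) -> tuple[np.ndarray, np.ndarray]:
    if list(geom.unit_ids) != list(matrix.unit_ids):
        idx = [geom.unit_ids.index(u) for u in matrix.unit_ids]
        geom = ArrayGeometry(list(matrix.unit_ids), geom.coordinates[idx], geom.pitch)
    D = geom.distance_matrix()
    mask = matrix.offdiag_mask() & np.isfinite(matrix.values)
    return matrix.values[mask], D[mask]


def spatial_footprint(
    matrix: _DirectedMatrix, geom: ArrayGeometry, bins: int | np.ndarray = 8
) -> dict[str, np.ndarray]:
    """Decay of connectivity with source-target distance.

    Pairs are grouped into Euclidean-distance bins; returns bin centers,
    mean, s.e.m. and counts per bin (empty bins are NaN, never interpolated).
    """
    vals, dist = _pair_arrays(matrix, geom)
    if np.isscalar(bins):
        edges = np.linspace(dist.min(), dist.max() + 1e-9, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    which = np.digitize(dist, edges[1:-1])
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = vals[which == b]
        count[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sem[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"centers": centers, "mean": mean, "sem": sem, "count": count, "edges": edges}


def residualize_distance(
    matrix: _DirectedMatrix, geom: ArrayGeometry, bins: int | np.ndarray = 8
) -> np.ndarray:
    """Bin-mean detrending: entry minus the mean footprint at its distance bin.

    Residuals have zero mean within each distance bin by construction; with a
    single bin (degenerate geometry) the global mean is removed, with a
    warning.
    """
    vals, dist = _pair_arrays(matrix, geom)
    fp = spatial_footprint(matrix, geom, bins)
    edges = fp["edges"]
    if len(edges) - 1 == 1 or np.unique(dist).size == 1:
        warnings.warn("single-distance geometry: residual = value - global mean")
    D = geom.distance_matrix() if list(geom.unit_ids) == list(matrix.unit_ids) else None
    if D is None:
        idx = [geom.unit_ids.index(u) for u in matrix.unit_ids]
        D = ArrayGeometry(list(matrix.unit_ids), geom.coordinates[idx], geom.pitch).distance_matrix()
    which = np.digitize(D, edges[1:-1])
    trend = np.where(np.isfinite(fp["mean"][which]), fp["mean"][which], np.nanmean(matrix.values))
    resid = matrix.values - trend
    resid[~(matrix.offdiag_mask() & np.isfinite(matrix.values))] = np.nan
    return resid


@dataclass
class PredictionReport:
    """Statistics linking resting-state connectivity to perturbation effects."""

    n_pairs: int
    pearson_r: float
    pearson_p: float
    regression_slope: float
    slope_p: float
    # mean IC over pairs with significant vs nonsignificant CF, and the test
    group_means_ic_by_cf: tuple[float, float] = (np.nan, np.nan)
    group_test_ic_by_cf: tuple[float, float] = (np.nan, np.nan)
    # mean CF over pairs with significant vs nonsignificant IC, and the test
    group_means_cf_by_ic: tuple[float, float] = (np.nan, np.nan)
    group_test_cf_by_ic: tuple[float, float] = (np.nan, np.nan)
    per_source: dict = field(default_factory=dict)
    gini_cf_per_source: dict = field(default_factory=dict)
    gini_ic_per_source: dict = field(default_factory=dict)
    residual: "PredictionReport | None" = None


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        return (np.nan, np.nan)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _column_gini(mat: _DirectedMatrix) -> dict[str, float]:
    out = {}
    for j, u in enumerate(mat.unit_ids):
        col = mat.values[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0 or np.all(col <= 0):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[u] = gini(col)
    return out


def prediction_tests(
    cf: CFMatrix, ic: ICMatrix, geom: ArrayGeometry | None = None, _residual_pass: bool = False
) -> PredictionReport:
    """CF-vs-IC prediction statistics over the shared ordered-pair set.

    Only pairs with both CF and IC defined enter: Pearson r (pooled), the
    pooled linear regression IC ~ CF, per-source regressions, Welch t-tests
    comparing IC across CF-significant vs -nonsignificant pairs (and CF
    across IC groups), plus per-source column Gini coefficients.  With a
    geometry, every statistic is recomputed on bin-mean distance residuals.
    """
    if list(cf.unit_ids) != list(ic.unit_ids):
        raise ValueError("CF and IC must cover the same units in the same order")
    valid = np.isfinite(cf.values) & np.isfinite(ic.values) & cf.offdiag_mask()
    f = cf.values[valid]
    s = ic.values[valid]
    if f.size < 3:
        raise ValueError("fewer than 3 valid pairs")
    r, rp = stats.pearsonr(f, s)
    reg = stats.linregress(f, s)
    cf_sig = cf.sig_mask[valid]
    ic_sig = ic.sig_mask[valid]

    def groups(vals, sig):
        a, b = vals[sig], vals[~sig]
        means = (float(a.mean()) if a.size else np.nan, float(b.mean()) if b.size else np.nan)
        return means, _welch(a, b)

    m_ic_by_cf, t_ic_by_cf = groups(s, cf_sig)
    m_cf_by_ic, t_cf_by_ic = groups(f, ic_sig)

    per_source = {}
    for j, u in enumerate(cf.unit_ids):
        col_ok = valid[:, j]
        if col_ok.sum() >= 3:
            res = stats.linregress(cf.values[col_ok, j], ic.values[col_ok, j])
            per_source[u] = {"slope": float(res.slope), "r": float(res.rvalue), "slope_p": float(res.pvalue)}

    report = PredictionReport(
        n_pairs=int(f.size),
        pearson_r=float(r),
        pearson_p=float(rp),
        regression_slope=float(reg.slope),
        slope_p=float(reg.pvalue),
        group_means_ic_by_cf=m_ic_by_cf,
        group_test_ic_by_cf=t_ic_by_cf,
        group_means_cf_by_ic=m_cf_by_ic,
        group_test_cf_by_ic=t_cf_by_ic,
        per_source=per_source,
        gini_cf_per_source=_column_gini(cf),
        gini_ic_per_source=_column_gini(ic),
    )
    if geom is not None and not _residual_pass:
        cf_res = CFMatrix(
            values=residualize_distance(cf, geom), unit_ids=list(cf.unit_ids),
            sig_mask=cf.sig_mask.copy(), meta=dict(cf.meta),
        )
        ic_res = ICMatrix(
            values=residualize_distance(ic, geom), unit_ids=list(ic.unit_ids),
            sig_mask=ic.sig_mask.copy(), n_trials=dict(ic.n_trials), window=ic.window,
        )
        report.residual = prediction_tests(cf_res, ic_res, geom=None, _residual_pass=True)
    return report


def cf_hierarchy_pca(cf: CFMatrix, n_clusters: int = 2, seed: int = 0) -> dict:
    """PCA of CF column vectors and 2-means clustering of the leading scores.

    On the ground-truth simulator, the driver (X) and driven (Y) subnetworks
    separate into two clusters of CF vectors.  Missing entries (diagonal) are
    imputed with the column mean of the defined entries before PCA.  Returns
    component scores, cluster labels per source unit, the silhouette score
    (NaN-flagged when the columns are degenerate), and explained variance.
    """
    n = cf.n_units
    if n < 3:
        raise ValueError("need at least 3 units for the hierarchy PCA")
    cols = cf.values.copy()
    for j in range(n):
        col = cols[:, j]
        fill = np.nanmean(col) if np.isfinite(col).any() else 0.0
        col[~np.isfinite(col)] = fill
    X = cols.T  # one row per source's CF vector
    if np.allclose(X, X[0], atol=1e-12):
        return {
            "scores": np.zeros((n, 2)),
            "labels": np.zeros(n, dtype=int),
            "silhouette": float("nan"),
            "explained_variance_ratio": np.zeros(2),
            "unit_ids": list(cf.unit_ids),
        }
    n_comp = min(2, n - 1)
    pca = PCA(n_components=n_comp, random_state=seed)
    scores = pca.fit_transform(X)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(scores)
    labels = km.labels_
    sil = float("nan")
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(scores, labels))
    return {
        "scores": scores,
        "labels": labels,
        "silhouette": sil,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "unit_ids": list(cf.unit_ids),
    }
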