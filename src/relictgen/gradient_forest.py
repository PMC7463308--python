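"""Gradient-forest allelic turnover and genomic vulnerability.

One regression forest is fitted per locus (population allele frequency on
climate predictors).  Raw split-impurity improvements are accumulated along
each predictor's gradient and combined across loci weighted by forest fit
quality (out-of-bag R^2, negatives truncated to 0) into monotone cumulative
importance curves F_p, scaled so each curve's total rise equals the
predictor's overall importance.  Overall predictor importance
uses joint permutation of predictor groups correlated above a threshold, so
collinear climate variables do not steal credit from one another.

Transforming a climate grid through the fitted curves maps every cell into
"genomic composition" space; genomic vulnerability is the per-cell Euclidean
distance between compositions under current and future climate — a
genotype-environment mismatch proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_association import SitePredictors
from .rasters import ClimateGrid

__all__ = ["GFModel", "fit_gf", "transform_climate", "genomic_vulnerability",
           "max_level"]

_N_GRID = 101


def max_level(n_sites: int) -> int:
    """Tree depth limit log2(0.368 n)/2 rounded down, floor 1."""
    return max(int(np.log2(max(0.368 * n_sites, 2.0)) / 2.0), 1)


@dataclass
class GFModel:
    """Per-predictor cumulative turnover curves and importances."""

    predictors: list[str]
    grid: dict[str, np.ndarray]          # gradient positions per predictor
    cumulative: dict[str, np.ndarray]    # F_p values on the grid (non-decreasing)
    importance: dict[str, float]
    locus_r2: pd.Series
    train_range: dict[str, tuple[float, float]]
    correlation_groups: list[list[str]] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def turnover(self, name: str, x, clamp_flag: bool = False):
        """F_p evaluated at ``x`` (clamped to the training gradient range)."""
        g, f = self.grid[name], self.cumulative[name]
        x = np.asarray(x, dtype=float)
        vals = np.interp(x, g, f)
        if clamp_flag:
            lo, hi = self.train_range[name]
            return vals, (x < lo) | (x > hi)
        return vals


def _correlation_groups(X: pd.DataFrame, threshold: float) -> list[list[str]]:
    names = list(X.columns)
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    if corr.ndim == 0:
        return [[names[0]]]
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if corr[i, j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, n in enumerate(names):
        groups.setdefault(find(i), []).append(n)
    return list(groups.values())


def _split_improvements(forest, n_features):
    """(feature, threshold, improvement) triples pooled over all trees."""
    feats, thresholds, improvements = [], [], []
    for est in forest.estimators_:
        t = est.tree_
        total_w = t.weighted_n_node_samples[0]
        for node in range(t.node_count):
            f = t.feature[node]
            if f < 0:
                continue
            left, right = t.children_left[node], t.children_right[node]
            imp = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[left] * t.impurity[left]
                - t.weighted_n_node_samples[right] * t.impurity[right]
            ) / total_w
            feats.append(f)
            thresholds.append(t.threshold[node])
            improvements.append(max(imp, 0.0))
    return (np.asarray(feats), np.asarray(thresholds), np.asarray(improvements))


def fit_gf(
    freqs: pd.DataFrame,
    predictors: SitePredictors,
    n_trees: int = 500,
    correlation_threshold: float = 0.5,
    rng=None,
) -> GFModel:
    """Fit per-locus regression forests and build turnover curves.

    ``freqs``: populations x loci allele-frequency table.  Requires at least
    6 populations; constant predictors are dropped with a warning.
    """
    from sklearn.ensemble import RandomForestRegressor

    seed = int(np.random.default_rng(rng).integers(2**31 - 1)) if not isinstance(rng, int) else rng
    common = [p for p in freqs.index if p in predictors.table.index]
    if len(common) < 6:
        raise ValueError("need at least 6 populations")
    X = predictors.table.loc[common].astype(float)
    const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if const:
        warnings.warn(f"dropping constant predictors: {const}")
        X = X.drop(columns=const)
    names = list(X.columns)
    groups = _correlation_groups(X, correlation_threshold)
    Xv = X.to_numpy()
    n = len(common)
    depth = max_level(n)

    raw_curves = {p: np.zeros(_N_GRID) for p in names}
    grids = {}
    edges = {}
    for k, p in enumerate(names):
        lo, hi = Xv[:, k].min(), Xv[:, k].max()
        pad = (hi - lo) * 1e-6 or 1.0
        e = np.linspace(lo - pad, hi + pad, _N_GRID + 1)
        edges[p] = e
        grids[p] = 0.5 * (e[:-1] + e[1:])

    r2 = {}
    perm_imp = {p: [] for p in names}
    rng_np = np.random.default_rng(seed)
    for locus in freqs.columns:
        y = freqs.loc[common, locus].to_numpy(dtype=float)
        if np.ptp(y[np.isfinite(y)]) == 0 or not np.isfinite(y).all():
            r2[locus] = 0.0
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_depth=depth, max_features=1.0 / 3.0,
            oob_score=True, bootstrap=True, random_state=int(rng_np.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(Xv, y)
        w = max(float(forest.oob_score_), 0.0)
        r2[locus] = w
        if w == 0.0:
            continue
        feats, ths, imps = _split_improvements(forest, len(names))
        for k, p in enumerate(names):
            sel = feats == k
            if sel.any():
                idx = np.clip(
                    np.searchsorted(edges[p], ths[sel]) - 1, 0, _N_GRID - 1
                )
                np.add.at(raw_curves[p], idx, w * imps[sel])
        # joint-permutation importance of correlated groups
        base = 1.0 - ((forest.predict(Xv) - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        for grp in groups:
            cols = [names.index(g) for g in grp]
            Xp = Xv.copy()
            perm = rng_np.permutation(n)
            Xp[:, cols] = Xv[perm][:, cols]
            drop = base - (
                1.0 - ((forest.predict(Xp) - y) ** 2).sum()
                / ((y - y.mean()) ** 2).sum()
            )
            for g in grp:
                perm_imp[g].append(w * max(drop, 0.0) / len(grp))

    importance = {
        p: float(np.mean(perm_imp[p])) if perm_imp[p] else 0.0 for p in names
    }
    cumulative = {}
    for p in names:
        # split thresholds fall midway between data points, so raw binned
        # improvements already localize turnover; the curve is scaled so its
        # total rise equals the predictor's overall importance
        cum = np.cumsum(raw_curves[p])
        total = cum[-1]
        if total > 0:
            cum = cum / total * importance[p]
        cumulative[p] = cum
    return GFModel(
        predictors=names, grid=grids, cumulative=cumulative,
        importance=importance,
        locus_r2=pd.Series(r2, name="oob_r2"),
        train_range={p: (float(X[p].min()), float(X[p].max())) for p in names},
        correlation_groups=groups,
        config={"n_trees": n_trees, "max_level": depth,
                "correlation_threshold": correlation_threshold,
                "n_gradient_bins": _N_GRID,
                "binning": "R2-weighted split improvements binned on a "
                           "101-point grid, scaled to overall importance"},
    )


def transform_climate(model: GFModel, grid: ClimateGrid):
    """Apply the turnover curves cellwise: composition grid + clamp flags."""
    comp = {}
    flags = np.zeros(grid.shape, dtype=bool)
    for p in model.predictors:
        if p not in grid.variables:
            raise KeyError(f"grid lacks variable {p!r}")
        vals, out_of_range = model.turnover(p, grid.variables[p], clamp_flag=True)
        comp[p] = np.where(grid.mask, vals, np.nan)
        flags |= out_of_range & grid.mask
    return comp, flags


def genomic_vulnerability(
    model: GFModel, grid_now: ClimateGrid, grid_future: ClimateGrid
) -> np.ndarray:
    """Per-cell Euclidean distance between current and future compositions.

    Masked cells propagate as NaN.  Raises on geometry mismatch.
    """
    if not grid_now.same_geometry(grid_future):
        raise ValueError("current and future grids differ in geometry")
    comp_now, _ = transform_climate(model, grid_now)
    comp_fut, _ = transform_climate(model, grid_future)
    sq = np.zeros(grid_now.shape)
    for p in model.predictors:
        sq += (comp_now[p] - comp_fut[p]) ** 2
    out = np.sqrt(sq)
    return np.where(grid_now.mask, out, np.nan)
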