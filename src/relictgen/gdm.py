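"""Generalized dissimilarity modelling of pairwise genetic differentiation.

GDM regresses a pairwise dissimilarity d_ij in [0, 1) on between-site
differences of monotone (I-spline) transforms of each predictor, through the
link d = 1 - exp(-eta) with eta >= 0:

    eta_ij = b0 + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|

Geographic distance ("GEO", great-circle km) enters as a predictor whose
spline is evaluated directly on the pairwise distance.  Coefficients are
constrained non-negative and fitted by non-negative least squares on the
link scale (y = -log(1 - d)); deviance explained is the percent reduction in
squared error relative to the intercept-only model on that scale.  The
maximum height of each fitted spline (the coefficient sum) measures the
amount of turnover attributed to that predictor.

Backward elimination repeatedly drops the least-important predictor whose
permutation p-value (site values permuted, model refitted) is not
significant, until all retained predictors are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .env_association import SitePredictors

__all__ = ["GDMModel", "ispline_basis", "fit_gdm", "backward_eliminate",
           "haversine_km"]

_EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _quantile_knots(x: np.ndarray, n_basis: int) -> np.ndarray:
    return np.quantile(x, np.linspace(0, 1, n_basis))


def ispline_basis(x, knots) -> np.ndarray:
    """Order-2 I-spline basis values at ``x`` for quantile ``knots``.

    Returns an (len(x), len(knots)) array of monotone non-decreasing basis
    functions, each 0 at the gradient minimum and 1 at the maximum.  Knot
    vector is (q1, q1, q2, ..., q_{K-1}, qK, qK); basis i integrates the
    order-2 M-spline supported on (t_i, t_{i+2}).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 2:
        raise ValueError("need at least 2 knots")
    t = np.concatenate([[knots[0]], knots, [knots[-1]]])
    out = np.zeros((len(x), K))
    for i in range(K):
        t0, t1, t2 = t[i], t[i + 1], t[i + 2]
        if t2 <= t0:  # degenerate (constant predictor)
            continue
        v = np.zeros(len(x))
        # integral of the order-2 M-spline on (t0, t2)
        if t1 > t0:
            seg = (x > t0) & (x < t1)
            v[seg] = (x[seg] - t0) ** 2 / ((t2 - t0) * (t1 - t0))
            v[x >= t1] = (t1 - t0) / (t2 - t0)
        if t2 > t1:
            seg = (x >= t1) & (x < t2)
            v[seg] = 1.0 - (t2 - x[seg]) ** 2 / ((t2 - t0) * (t2 - t1))
        v[x >= t2] = 1.0
        out[:, i] = v
    return out


@dataclass
class GDMModel:
    """Fitted GDM: intercept, per-predictor I-spline coefficients and knots."""

    intercept: float
    coefficients: dict[str, np.ndarray]
    knots: dict[str, np.ndarray]
    deviance_explained: float
    importance: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    model_p_value: float | None = None
    predictors: list[str] = field(default_factory=list)

    def transform(self, name: str, x) -> np.ndarray:
        """Fitted spline f_p(x) = sum_k beta_pk I_pk(x) (max = importance)."""
        basis = ispline_basis(x, self.knots[name])
        return basis @ self.coefficients[name]

    def linear_predictor(self, pair_design: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(pair_design), self.intercept)
        for p in self.predictors:
            cols = [f"{p}|{k}" for k in range(len(self.coefficients[p]))]
            eta += pair_design[cols].to_numpy() @ self.coefficients[p]
        return eta

    def predict(self, pair_design: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-self.linear_predictor(pair_design))


def _pair_table(response: pd.DataFrame, predictors: SitePredictors,
                coords: dict[str, tuple[float, float]] | None, n_basis: int):
    """Site-pair response vector, design matrix, and knots."""
    sites = [s for s in response.index if s in predictors.table.index]
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    tab = predictors.table.loc[sites]
    if not np.isfinite(tab.to_numpy(dtype=float)).all():
        raise ValueError("non-finite predictor values")
    names = list(tab.columns)
    knots: dict[str, np.ndarray] = {}
    site_basis: dict[str, np.ndarray] = {}
    for p in names:
        x = tab[p].to_numpy(dtype=float)
        knots[p] = _quantile_knots(x, n_basis)
        site_basis[p] = ispline_basis(x, knots[p])
    use_geo = coords is not None
    if use_geo:
        lat = np.array([coords[s][0] for s in sites])
        lon = np.array([coords[s][1] for s in sites])
        dmat = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    ii, jj = np.triu_indices(len(sites), k=1)
    y = np.clip(response.loc[sites, sites].to_numpy(dtype=float)[ii, jj], 0.0, None)
    cols = {}
    for p in names:
        diff = np.abs(site_basis[p][ii] - site_basis[p][jj])
        for k in range(diff.shape[1]):
            cols[f"{p}|{k}"] = diff[:, k]
    if use_geo:
        gd = dmat[ii, jj]
        knots["GEO"] = _quantile_knots(gd, n_basis)
        gb = ispline_basis(gd, knots["GEO"])
        for k in range(gb.shape[1]):
            cols[f"GEO|{k}"] = gb[:, k]
        names = names + ["GEO"]
    design = pd.DataFrame(cols)
    return y, design, knots, names, sites


def _nnls_fit(y: np.ndarray, design: pd.DataFrame, names, knots, n_basis):
    ylink = -np.log(np.clip(1.0 - y, 1e-9, None))
    X = np.column_stack([np.ones(len(y)), design.to_numpy()])
    beta, _ = nnls(X, ylink)
    resid = ylink - X @ beta
    sst = float(((ylink - ylink.mean()) ** 2).sum())
    dev = 100.0 * (1.0 - float((resid**2).sum()) / sst) if sst > 0 else 0.0
    coefs = {}
    pos = 1
    for p in names:
        k = len(knots[p])
        coefs[p] = beta[pos : pos + k].copy()
        pos += k
    importance = {p: float(c.sum()) for p, c in coefs.items()}
    return float(beta[0]), coefs, importance, dev


def fit_gdm(
    response: pd.DataFrame,
    predictors: SitePredictors,
    coords: dict[str, tuple[float, float]] | None = None,
    n_basis: int = 3,
) -> GDMModel:
    """Fit a GDM to a symmetric pairwise dissimilarity matrix.

    ``response`` rows/columns are site (population) labels; values should lie
    in [0, 1) — negatives (e.g. pairwise Phi_ST estimates) are clamped to 0.
    ``coords`` (site -> (lat, lon)) adds great-circle distance as the GEO
    predictor.
    """
    resp = response.copy()
    if not np.allclose(resp.to_numpy(dtype=float), resp.to_numpy(dtype=float).T,
                       equal_nan=True):
        raise ValueError("response matrix must be symmetric")
    y, design, knots, names, _ = _pair_table(resp, predictors, coords, n_basis)
    intercept, coefs, importance, dev = _nnls_fit(y, design, names, knots, n_basis)
    return GDMModel(
        intercept=intercept, coefficients=coefs, knots=knots,
        deviance_explained=dev, importance=importance, predictors=names,
    )


def backward_eliminate(
    response: pd.DataFrame,
    predictors: SitePredictors,
    coords: dict[str, tuple[float, float]] | None = None,
    n_basis: int = 3,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng=None,
):
    """Backward elimination with per-variable permutation significance.

    Each round fits the current model, permutes each variable's site values
    ``n_perm`` times (refitting each time), and computes
    p = (#{permuted deviance >= observed deviance} + 1)/(n_perm + 1).  The
    lowest-importance non-significant variable is dropped; iteration stops
    when every retained variable is significant (or none remain, returning an
    intercept-only model with a warning flag in the trace).  The full-model p
    permutes all predictors jointly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    current = SitePredictors(predictors.table.copy(), dict(predictors.units))
    cur_coords = dict(coords) if coords else None
    trace: list[dict] = []

    def fit_perm(tab: pd.DataFrame, crd) -> float:
        y, design, knots, names, _ = _pair_table(
            response, SitePredictors(tab), crd, n_basis
        )
        return _nnls_fit(y, design, names, knots, n_basis)[3]

    while True:
        model = fit_gdm(response, current, cur_coords, n_basis)
        sites = [s for s in response.index if s in current.table.index]
        # permutation p-value per retained variable
        pvals: dict[str, float] = {}
        for var in model.predictors:
            ge = 0
            for _ in range(n_perm):
                tab = current.table.copy()
                crd = cur_coords
                if var == "GEO":
                    perm = rng.permutation(sites)
                    crd = {s: cur_coords[q] for s, q in zip(sites, perm)}
                else:
                    tab[var] = tab[var].to_numpy()[rng.permutation(len(tab))]
                ge += fit_perm(tab, crd) >= model.deviance_explained
            pvals[var] = (ge + 1) / (n_perm + 1)
        model.p_values = pvals
        # full-model significance: all predictors permuted jointly
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(current.table))
            tab = current.table.iloc[perm].set_index(current.table.index)
            crd = cur_coords
            if cur_coords is not None:
                perm_sites = rng.permutation(sites)
                crd = {s: cur_coords[q] for s, q in zip(sites, perm_sites)}
            ge += fit_perm(tab, crd) >= model.deviance_explained
        model.model_p_value = (ge + 1) / (n_perm + 1)

        not_sig = [v for v in model.predictors if pvals[v] >= alpha]
        trace.append({
            "predictors": list(model.predictors),
            "deviance_explained": model.deviance_explained,
            "p_values": dict(pvals),
            "dropped": None,
        })
        if not not_sig:
            return model, trace
        drop = min(not_sig, key=lambda v: model.importance[v])
        trace[-1]["dropped"] = drop
        if drop == "GEO":
            cur_coords = None
        else:
            current = SitePredictors(
                current.table.drop(columns=[drop]), dict(current.units)
            )
        if current.table.shape[1] == 0 and cur_coords is None:
            # all variables eliminated: intercept-only
            import warnings

            warnings.warn("all predictors eliminated; returning intercept-only model")
            y = np.clip(
                response.to_numpy(dtype=float)[np.triu_indices(len(response), 1)],
                0, None,
            )
            ylink = -np.log(np.clip(1 - y, 1e-9, None))
            model = GDMModel(
                intercept=float(max(ylink.mean(), 0.0)), coefficients={},
                knots={}, deviance_explained=0.0, importance={}, predictors=[],
            )
            trace.append({"predictors": [], "deviance_explained": 0.0,
                          "p_values": {}, "dropped": None})
            return model, trace
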