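"""Reference-table approximate Bayesian computation.

Workflow: draw parameters from the priors, simulate unlinked-SNP datasets,
reduce each to a fixed summary-statistic vector, and compare the observed
vector against the reference table — scenario choice by rejection or
multinomial logistic regression on the retained nearest rows, parameter
estimation by local-linear regression with a logit transform to the prior
bounds, and posterior-predictive model checking in PCA space.

The summary registry is the unlinked-SNP canon: per group the proportion of
monomorphic loci and the mean and variance of unbiased gene diversity; per
group pair the Hudson FST (ratio of averages), Nei's standard genetic
distance, and the proportion of loci monomorphic in the pooled pair.  An
admixture-sensitive three-group statistic (an f3-style product of frequency
differences) is available but off by default.  The registry in use is
recorded on every reference table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent_sim import (
    ScenarioSpec,
    _as_rng,
    sample_prior,
    simulate_group_counts,
)
from .genotype_io import MISSING, PopulationMap, SNPMatrix

__all__ = [
    "SummaryVector",
    "ReferenceTable",
    "PosteriorEstimate",
    "summarize",
    "summarize_counts",
    "build_reference",
    "model_posterior",
    "cv_model_selection",
    "estimate_params",
    "cv_estimation",
    "model_check_pca",
    "generations_to_years",
]


@dataclass
class SummaryVector:
    names: list[str]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


@dataclass
class ReferenceTable:
    """Per-row scenario id, parameter draw, and summary vector."""

    scenarios: np.ndarray            # (n,) str
    params: pd.DataFrame             # (n, n_params); NaN where not in scenario
    summaries: pd.DataFrame          # (n, n_stats)
    priors: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    registry: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scenarios)

    def restrict(self, scenario: str) -> "ReferenceTable":
        mask = self.scenarios == scenario
        params = self.params.loc[mask].dropna(axis=1, how="all")
        return ReferenceTable(
            self.scenarios[mask], params.reset_index(drop=True),
            self.summaries.loc[mask].reset_index(drop=True),
            self.priors, self.registry,
        )

    def drop_rows(self, idx) -> "ReferenceTable":
        mask = np.ones(len(self), dtype=bool)
        mask[np.asarray(idx)] = False
        return ReferenceTable(
            self.scenarios[mask], self.params.loc[mask].reset_index(drop=True),
            self.summaries.loc[mask].reset_index(drop=True),
            self.priors, self.registry,
        )


@dataclass
class PosteriorEstimate:
    """Equal-tailed posterior quantiles per parameter."""

    table: pd.DataFrame              # index: parameter; cols median, q2.5, q97.5
    method: str


# ---------------------------------------------------------------------------
# Summary statistics


def _group_summaries(counts: np.ndarray, sizes: np.ndarray, names: list[str],
                     with_f3: bool = False) -> SummaryVector:
    """Summaries from per-group derived counts (G x L) and gene counts.

    ``sizes`` may be (G,) or per-locus (G, L) to honour missing data.
    """
    counts = np.asarray(counts, dtype=float)
    G, L = counts.shape
    n = np.broadcast_to(
        np.asarray(sizes, dtype=float).reshape(G, -1), counts.shape
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1), np.nan)
        h = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1e-12)
    mono = (counts == 0) | (counts == n)
    vals: list[float] = []
    out_names: list[str] = []
    for g in range(G):
        ok = n[g] >= 2
        vals += [
            float(np.mean(mono[g, ok])) if ok.any() else 1.0,
            float(np.nanmean(h[g, ok])) if ok.any() else 0.0,
            float(np.nanvar(h[g, ok])) if ok.any() else 0.0,
        ]
        out_names += [f"propmono_{names[g]}", f"meanH_{names[g]}", f"varH_{names[g]}"]
    for a in range(G):
        for b in range(a + 1, G):
            ok = (n[a] >= 2) & (n[b] >= 2)
            pa, pb = p[a, ok], p[b, ok]
            na, nb = n[a, ok], n[b, ok]
            num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
            den = pa * (1 - pb) + pb * (1 - pa)
            fst = float(num.sum() / den.sum()) if den.sum() > 0 else 0.0
            jab = (pa * pb + (1 - pa) * (1 - pb)).sum()
            ja = (pa**2 + (1 - pa) ** 2).sum()
            jb = (pb**2 + (1 - pb) ** 2).sum()
            nei = float(-np.log(jab / np.sqrt(ja * jb))) if jab > 0 else 10.0
            pairmono = float(np.mean(mono[a, ok] & mono[b, ok] & (pa == pb)))
            vals += [fst, nei, pairmono]
            pair = f"{names[a]}_{names[b]}"
            out_names += [f"fst_{pair}", f"nei_{pair}", f"propmono_{pair}"]
    if with_f3 and G >= 3:
        for c in range(G):
            rest = [g for g in range(G) if g != c]
            for i, a in enumerate(rest):
                for b in rest[i + 1:]:
                    ok = (n[a] >= 2) & (n[b] >= 2) & (n[c] >= 2)
                    f3 = float(np.mean((p[c, ok] - p[a, ok]) * (p[c, ok] - p[b, ok])))
                    vals.append(f3)
                    out_names.append(f"f3_{names[c]};{names[a]},{names[b]}")
    return SummaryVector(out_names, np.asarray(vals))


def summarize_counts(counts, sizes, group_names=None, with_f3=False) -> SummaryVector:
    counts = np.asarray(counts, dtype=float)
    if group_names is None:
        group_names = [f"g{i}" for i in range(counts.shape[0])]
    return _group_summaries(counts, sizes, list(group_names), with_f3)


def summarize(m: SNPMatrix, pmap: PopulationMap, with_f3: bool = False) -> SummaryVector:
    """Summary vector of an observed dataset; identical registry and code path
    as the simulated datasets (missing data enter via per-locus gene counts)."""
    gidx = pmap.group_indices(m)
    names = list(gidx)
    counts = np.empty((len(names), m.n_loci))
    sizes = np.empty((len(names), m.n_loci))
    for i, g in enumerate(names):
        sub = m.genotypes[gidx[g]]
        obs = sub != MISSING
        sizes[i] = 2 * obs.sum(axis=0)
        counts[i] = np.where(obs, sub, 0).sum(axis=0)
        if (sizes[i] < 2).all():
            raise ValueError(f"group {g!r} has fewer than 2 observed genes")
    return _group_summaries(counts, sizes, names, with_f3)


# ---------------------------------------------------------------------------
# Reference table


def build_reference(
    specs: list[ScenarioSpec], n_per_scenario: int, n_loci: int, rng,
    with_f3: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` draws per scenario and summarize each."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    rng = _as_rng(rng)
    scen_ids: list[str] = []
    param_rows: list[dict[str, float]] = []
    summ_rows: list[np.ndarray] = []
    registry: list[str] = []
    for spec in specs:
        for _ in range(n_per_scenario):
            draw = sample_prior(spec, rng)
            counts, sizes = simulate_group_counts(spec, draw, n_loci, rng)
            sv = summarize_counts(counts, sizes, spec.groups, with_f3)
            registry = sv.names
            scen_ids.append(spec.name)
            param_rows.append(draw.values)
            summ_rows.append(sv.values)
    summaries = pd.DataFrame(np.vstack(summ_rows), columns=registry)
    keep = ~summaries.isna().any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} rows with non-finite summaries")
    return ReferenceTable(
        scenarios=np.asarray(scen_ids)[keep.to_numpy()],
        params=pd.DataFrame(param_rows).loc[keep].reset_index(drop=True),
        summaries=summaries.loc[keep].reset_index(drop=True),
        priors={s.name: dict(s.priors) for s in specs},
        registry=registry,
    )


def concat_references(tables: list[ReferenceTable]) -> ReferenceTable:
    """Merge chunked reference tables (same registry)."""
    priors: dict = {}
    for t in tables:
        priors.update(t.priors)
    return ReferenceTable(
        np.concatenate([t.scenarios for t in tables]),
        pd.concat([t.params for t in tables], ignore_index=True),
        pd.concat([t.summaries for t in tables], ignore_index=True),
        priors, tables[0].registry,
    )


# ---------------------------------------------------------------------------
# Scenario choice


def _standardize(ref_summ: pd.DataFrame, observed: np.ndarray):
    X = ref_summ.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    mu = X.mean(axis=0)
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    obs = (np.asarray(observed, dtype=float)[keep] - mu[keep]) / sd[keep]
    return Xs, obs


def _observed_vector(observed, ref: ReferenceTable) -> np.ndarray:
    if isinstance(observed, SummaryVector):
        if observed.names != list(ref.summaries.columns):
            raise ValueError("observed summary registry differs from reference")
        return observed.values
    return np.asarray(observed, dtype=float)


def model_posterior(
    ref: ReferenceTable, observed, tolerance: float, method: str = "mnlogit",
) -> dict:
    """Posterior scenario probabilities at the given tolerance.

    Retains the nearest ``tolerance`` fraction of rows by Euclidean distance on
    SD-standardized summaries.  ``rejection`` reports scenario frequencies
    among retained rows; ``mnlogit``/``neuralnet`` fit a classifier on the
    retained rows and evaluate it at the observed point.  Returns
    ``{"probabilities": {...}, "bayes_factors": {...}}``.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    labels = np.unique(ref.scenarios)
    if len(labels) < 2:
        raise ValueError("reference table needs >= 2 scenarios")
    obs = _observed_vector(observed, ref)
    Xs, obs_s = _standardize(ref.summaries, obs)
    d = np.sqrt(((Xs - obs_s) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(d))), len(labels))
    kept = np.argsort(d, kind="stable")[:n_keep]
    y = ref.scenarios[kept]
    if method == "rejection":
        probs = {lab: float(np.mean(y == lab)) for lab in labels}
        missing = [lab for lab, p in probs.items() if p == 0]
        if missing:
            warnings.warn(f"scenarios absent from retained set: {missing}")
    elif method in ("mnlogit", "neuralnet"):
        if len(np.unique(y)) < 2:
            probs = {lab: float(np.mean(y == lab)) for lab in labels}
        else:
            if method == "mnlogit":
                from sklearn.linear_model import LogisticRegression

                clf = LogisticRegression(max_iter=2000)
            else:
                from sklearn.neural_network import MLPClassifier

                clf = MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000,
                                    random_state=0)
            clf.fit(Xs[kept], y)
            pr = clf.predict_proba(obs_s.reshape(1, -1))[0]
            probs = {lab: 0.0 for lab in labels}
            probs.update(dict(zip(clf.classes_, map(float, pr))))
    else:
        raise ValueError(f"unknown method {method!r}")
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    eps = 1e-12
    bf = {
        (i, j): (probs[i] + eps) / (probs[j] + eps)
        for i in labels for j in labels if i != j
    }
    return {"probabilities": probs, "bayes_factors": bf}


def cv_model_selection(
    ref: ReferenceTable, n_pods_per_scenario: int, tolerance: float,
    method: str = "mnlogit", rng=None,
) -> dict:
    """Leave-one-out scenario classification over pseudo-observed rows.

    Each pod row is held out of the training table, classified, and scored by
    argmax posterior.  Returns the confusion matrix (rows = truth) and the
    mean correct-identification rate.
    """
    rng = _as_rng(rng)
    labels = list(np.unique(ref.scenarios))
    pods: list[int] = []
    for lab in labels:
        rows = np.flatnonzero(ref.scenarios == lab)
        if n_pods_per_scenario > len(rows):
            raise ValueError("n_pods_per_scenario exceeds available rows")
        pods += list(rng.choice(rows, size=n_pods_per_scenario, replace=False))
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for row in pods:
        train = ref.drop_rows([row])
        obs = ref.summaries.iloc[row].to_numpy()
        res = model_posterior(train, obs, tolerance, method)
        pred = max(res["probabilities"], key=res["probabilities"].get)
        confusion.loc[ref.scenarios[row], pred] += 1
    rate = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    return {"confusion": confusion, "rate": rate}


# ---------------------------------------------------------------------------
# Parameter estimation


def _logit(x, lo, hi):
    z = np.clip((x - lo) / (hi - lo), 1e-10, 1 - 1e-10)
    return np.log(z / (1 - z))


def _inv_logit(y, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-y))


def _weighted_quantiles(x, w, qs):
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw = (cw - 0.5 * w) / w.sum()
    return np.interp(qs, cw, x)


def estimate_params(
    ref_scenario: ReferenceTable, observed, tolerance: float = 0.01,
    regression: str = "loclinear", transform: str = "logit",
) -> PosteriorEstimate:
    """Posterior quantiles for one scenario's parameters.

    Retains the nearest ``tolerance`` fraction of rows, Epanechnikov-weights
    them by distance, optionally logit-transforms each parameter to its prior
    bounds, and (for ``loclinear``) adjusts values by a weighted local-linear
    regression on the summaries evaluated at the observed point.  Reports
    weighted equal-tailed 2.5/50/97.5% quantiles.
    """
    labels = np.unique(ref_scenario.scenarios)
    if len(labels) != 1:
        raise ValueError("restrict the reference table to a single scenario first")
    priors = ref_scenario.priors.get(labels[0], {})
    obs = _observed_vector(observed, ref_scenario)
    Xs, obs_s = _standardize(ref_scenario.summaries, obs)
    d = np.sqrt(((Xs - obs_s) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(d))), 2)
    kept = np.argsort(d, kind="stable")[:n_keep]
    dmax = d[kept].max()
    if dmax == 0:
        w = np.ones(len(kept))
    else:
        w = 1.0 - (d[kept] / (dmax * (1 + 1e-12))) ** 2
        w = np.maximum(w, 1e-12)
    rows = []
    method_tag = "rejection" if regression == "none" else "loclinear"
    for param in ref_scenario.params.columns:
        theta = ref_scenario.params[param].to_numpy(dtype=float)[kept]
        lo, hi = priors.get(param, (np.min(theta), np.max(theta)))
        if transform == "logit" and hi > lo:
            th = _logit(theta, lo, hi)
        else:
            th = theta.copy()
        adj = th
        if regression == "loclinear":
            # weighted design centred at the observed point: the intercept is
            # then the regression fit at the observation; collinear summaries
            # resolve to the minimum-norm solution
            X = np.column_stack([np.ones(len(kept)), Xs[kept] - obs_s])
            sw = np.sqrt(w)
            try:
                beta, _, _, _ = np.linalg.lstsq(X * sw[:, None], th * sw,
                                                rcond=None)
                if not np.all(np.isfinite(beta)):
                    raise np.linalg.LinAlgError
                adj = beta[0] + (th - X @ beta)
            except np.linalg.LinAlgError:
                warnings.warn("singular local-linear system; falling back to rejection")
                method_tag = "rejection"
                adj = th
        qs = _weighted_quantiles(adj, w, np.array([0.025, 0.5, 0.975]))
        if transform == "logit" and hi > lo:
            qs = _inv_logit(qs, lo, hi)
        rows.append({"parameter": param, "q2.5": qs[0], "median": qs[1],
                     "q97.5": qs[2]})
    table = pd.DataFrame(rows).set_index("parameter")[["median", "q2.5", "q97.5"]]
    return PosteriorEstimate(table=table, method=method_tag)


def cv_estimation(
    ref_scenario: ReferenceTable, n_pods: int, tolerances, methods, rng=None,
) -> pd.DataFrame:
    """Prediction error mean((est - true)^2)/var(true) per parameter, method,
    and tolerance, over held-out pseudo-observed rows."""
    rng = _as_rng(rng)
    rows_all = rng.choice(len(ref_scenario), size=n_pods, replace=False)
    records = []
    truth = ref_scenario.params
    var_true = truth.var(ddof=0)
    for method in methods:
        for tol in tolerances:
            est = {p: [] for p in truth.columns}
            for row in rows_all:
                train = ref_scenario.drop_rows([row])
                obs = ref_scenario.summaries.iloc[row].to_numpy()
                pe = estimate_params(
                    train, obs, tolerance=tol,
                    regression="none" if method == "rejection" else method,
                )
                for p in truth.columns:
                    est[p].append(pe.table.loc[p, "median"])
            for p in truth.columns:
                err = np.mean(
                    (np.asarray(est[p]) - truth[p].to_numpy()[rows_all]) ** 2
                ) / var_true[p]
                records.append({"parameter": p, "method": method,
                                "tolerance": tol, "error": float(err)})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Model checking & units


def model_check_pca(ref_prior: ReferenceTable, posterior_draws: np.ndarray,
                    observed) -> dict:
    """Project prior-predictive, posterior-predictive, and observed summaries
    onto the prior PCA plane; flag whether the observed point falls inside the
    axis-aligned [1%, 99%] quantile box of each cloud."""
    from sklearn.decomposition import PCA

    obs = _observed_vector(observed, ref_prior)
    X = ref_prior.summaries.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    mu = X.mean(axis=0)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    pca = PCA(n_components=2)
    prior_xy = pca.fit_transform(Z)
    post = np.asarray(posterior_draws, dtype=float)
    post_xy = pca.transform((post[:, keep] - mu[keep]) / sd[keep])
    obs_xy = pca.transform(((obs[keep] - mu[keep]) / sd[keep]).reshape(1, -1))[0]

    def inside(cloud):
        lo = np.quantile(cloud, 0.01, axis=0)
        hi = np.quantile(cloud, 0.99, axis=0)
        return bool(np.all(obs_xy >= lo) and np.all(obs_xy <= hi))

    return {
        "prior_coords": prior_xy,
        "posterior_coords": post_xy,
        "observed_coords": obs_xy,
        "inside_prior": inside(prior_xy),
        "inside_posterior": inside(post_xy),
    }


def generations_to_years(t_generations, generation_time: float = 10.0):
    """Convert generations to years (default generation time 10 years)."""
    return np.asarray(t_generations, dtype=float) * generation_time
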