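"""Climate-association classification of outlier loci.

Population alternate-allele frequencies are regressed (ordinary least
squares, all predictors jointly) on a set of bioclimatic variables; a locus
qualifies as "adaptive" when the adjusted R-squared exceeds a threshold and
at least one predictor coefficient is individually significant.  No
multiple-testing correction is applied across loci by default (the joint
R2/p rule is per locus); pass ``correct_loci=True`` to BH-adjust the
per-locus minimum p-values as a caveat-driven option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype_io import MISSING, PopulationMap, SNPMatrix

__all__ = ["SitePredictors", "AdaptiveScanResult", "population_allele_freqs",
           "mlr_adaptive_scan"]


@dataclass
class SitePredictors:
    """Per-population values of bioclimatic variables (+ coordinates).

    ``table`` is indexed by population with one column per variable
    (temperature in degrees C, precipitation in mm by WorldClim convention);
    ``units`` records the unit string per variable.
    """

    table: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise ValueError("predictor table contains missing values")

    def subset(self, variables) -> "SitePredictors":
        return SitePredictors(self.table[list(variables)].copy(),
                              {v: self.units.get(v, "") for v in variables})


@dataclass
class AdaptiveScanResult:
    """Per-locus OLS fit summary; ``adaptive`` is the flagged locus set."""

    table: pd.DataFrame
    adaptive: set[str] = field(default_factory=set)
    degenerate: set[str] = field(default_factory=set)


def population_allele_freqs(m: SNPMatrix, pmap: PopulationMap) -> pd.DataFrame:
    """Alternate-allele frequency per population x locus over observed genes."""
    out = {}
    for pop, idx in pmap.pop_indices(m).items():
        sub = m.genotypes[idx]
        obs = sub != MISSING
        genes = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[pop] = np.where(genes > 0, np.where(obs, sub, 0).sum(axis=0) / np.maximum(genes, 1), np.nan)
    return pd.DataFrame(out, index=m.locus_ids).T


def mlr_adaptive_scan(
    freqs: pd.DataFrame,
    predictors: SitePredictors,
    r2_threshold: float = 0.5,
    alpha: float = 0.05,
    correct_loci: bool = False,
) -> AdaptiveScanResult:
    """Joint OLS of per-population allele frequency on all predictors.

    ``freqs``: populations x loci (as from :func:`population_allele_freqs`).
    Requires n_populations > n_predictors + 1.  Constant-frequency loci are
    skipped and reported as degenerate.
    """
    common = [p for p in freqs.index if p in predictors.table.index]
    X = predictors.table.loc[common]
    n, k = len(common), X.shape[1]
    if n <= k + 1:
        raise ValueError(
            f"need more populations ({n}) than predictors + 1 ({k + 1})"
        )
    Xd = sm.add_constant(X.to_numpy(dtype=float))
    rows = []
    degenerate: set[str] = set()
    adaptive: set[str] = set()
    for locus in freqs.columns:
        y = freqs.loc[common, locus].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() <= k + 1 or np.ptp(y[ok]) == 0:
            degenerate.add(locus)
            rows.append({"locus": locus, "r2_adj": np.nan, "flag": False,
                         "degenerate": True, "significant_vars": ""})
            continue
        fit = sm.OLS(y[ok], Xd[ok]).fit()
        pvals = dict(zip(X.columns, fit.pvalues[1:]))
        sig = [v for v, pv in pvals.items() if pv < alpha]
        row = {"locus": locus, "r2_adj": float(fit.rsquared_adj),
               "degenerate": False, "significant_vars": ",".join(sig),
               "min_p": float(min(fit.pvalues[1:]))}
        row.update({f"p_{v}": float(pv) for v, pv in pvals.items()})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("locus")
    if correct_loci and "min_p" in table:
        from statsmodels.stats.multitest import multipletests

        fin = table["min_p"].notna()
        adj = np.full(len(table), np.nan)
        if fin.any():
            adj[fin.to_numpy()] = multipletests(
                table.loc[fin, "min_p"], method="fdr_bh"
            )[1]
        table["min_p_adj"] = adj
        sig_ok = table["min_p_adj"] < alpha
    else:
        sig_ok = table["significant_vars"].fillna("") != ""
    flag = (table["r2_adj"] > r2_threshold) & sig_ok & ~table["degenerate"]
    table["flag"] = flag.fillna(False)
    adaptive = set(table.index[table["flag"]])
    return AdaptiveScanResult(table=table, adaptive=adaptive, degenerate=degenerate)
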