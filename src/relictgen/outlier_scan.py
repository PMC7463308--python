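"""FST-outlier detection.

Two scans, intersected for a conservative call set:

* ``bayescan_scan`` — Bayesian decomposition of locus-population FST into a
  locus effect alpha_i (selection) and a population effect beta_j (drift),
  FST_ij = 1/(1 + exp(-(alpha_i + beta_j))).  Population allele counts are
  beta-binomial given the ancestral frequency p_i and FST_ij; a
  reversible-jump MCMC toggles inclusion of alpha_i with configurable prior
  odds for neutrality.  Loci are flagged when the q-value (cumulative mean of
  1 - posterior inclusion probability over loci ranked by that probability)
  falls below the threshold with alpha > 0.

* ``fdist_scan`` — simulation of a neutral (heterozygosity, FST) null under a
  finite-island coalescent with migration tuned to the observed global FST;
  per-locus p-values are ranks within heterozygosity bins, adjusted by
  Benjamini-Hochberg.

Both scans are invariant to allele relabelling and population order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, expit

from . import _kernel
from .genotype_io import MISSING, PopulationMap, SNPMatrix
from .coalescent_sim import _as_rng

__all__ = ["OutlierResult", "bayescan_scan", "fdist_scan", "intersect_outliers"]


@dataclass
class OutlierResult:
    """Per-locus report of one scan; ``flagged`` is the outlier id set."""

    scan: str
    table: pd.DataFrame
    flagged: set[str] = field(default_factory=set)
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared helpers


def _pop_allele_counts(m: SNPMatrix, pmap: PopulationMap):
    """(alt counts, gene counts) per locus x population, pairwise deletion."""
    pidx = pmap.pop_indices(m)
    pops = list(pidx)
    L = m.n_loci
    alt = np.empty((L, len(pops)))
    genes = np.empty((L, len(pops)))
    for j, p in enumerate(pops):
        sub = m.genotypes[pidx[p]]
        obs = sub != MISSING
        genes[:, j] = 2 * obs.sum(axis=0)
        alt[:, j] = np.where(obs, sub, 0).sum(axis=0)
    return alt, genes, pops


def _anova_fst(alt: np.ndarray, genes: np.ndarray):
    """Per-locus one-way ANOVA FST on genes (allele indicator data).

    Returns (fst, heterozygosity 2*pbar*(1-pbar)); loci with no variation or
    a single informative population give NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(genes > 0, alt / np.maximum(genes, 1), np.nan)
    N = genes.sum(axis=1)
    r = (genes > 0).sum(axis=1)
    pbar = alt.sum(axis=1) / N
    with np.errstate(invalid="ignore", divide="ignore"):
        msa = np.nansum(genes * (p - pbar[:, None]) ** 2, axis=1) / (r - 1)
        ssw = np.nansum(genes * p * (1 - p), axis=1)
        dfw = N - r
        msw = np.where(dfw > 0, ssw / np.maximum(dfw, 1), np.nan)
        nc = (N - (genes**2).sum(axis=1) / N) / (r - 1)
        sa = (msa - msw) / nc
        fst = sa / (sa + msw)
    he = 2 * pbar * (1 - pbar)
    bad = (r < 2) | (he == 0) | ~np.isfinite(fst)
    fst = np.where(bad, np.nan, fst)
    return fst, he


# ---------------------------------------------------------------------------
# BayeScan-style scan


def _betabin_loglik(alt, genes, p, alpha_delta, beta):
    """log L matrix (L x P); theta_ij = exp(-(alpha_i*delta_i + beta_j))."""
    theta = np.exp(-(alpha_delta[:, None] + beta[None, :]))
    a1 = theta * p[:, None]
    a2 = theta * (1.0 - p[:, None])
    return (
        gammaln(alt + a1) - gammaln(a1)
        + gammaln(genes - alt + a2) - gammaln(a2)
        + gammaln(theta) - gammaln(genes + theta)
    )


def bayescan_scan(
    m: SNPMatrix,
    pmap: PopulationMap,
    prior_odds: float = 10.0,
    n_iter: int = 5000,
    thin: int = 20,
    n_pilot: int = 20,
    pilot_len: int = 5000,
    burnin: int = 50000,
    rng=None,
    q_threshold: float = 0.001,
) -> OutlierResult:
    """Reversible-jump MCMC scan for locus-specific selection effects.

    Chain-length defaults mirror heavy production settings; shorter chains are
    adequate for moderate locus counts.  ``n_iter`` counts retained samples
    (every ``thin`` sweeps after ``burnin``).
    """
    rng = _as_rng(rng)
    alt, genes, pops = _pop_allele_counts(m, pmap)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    L, P = alt.shape
    pi_incl = 1.0 / (1.0 + prior_odds)

    # state
    p = np.clip((alt.sum(axis=1) + 1.0) / (genes.sum(axis=1) + 2.0), 1e-4, 1 - 1e-4)
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(P, -1.0)
    sd_alpha_prior, beta_mu, beta_sd = 1.0, -1.0, 1.8
    s_p = np.full(L, 0.5)
    s_a = np.full(L, 0.5)
    s_b = np.full(P, 0.2)

    ll = _betabin_loglik(alt, genes, p, alpha * delta, beta)

    def sweep(adapt_acc=None):
        nonlocal p, alpha, delta, beta, ll
        # ancestral frequency p_i (uniform prior -> logit-space Jacobian)
        z = np.log(p / (1 - p))
        z_new = z + rng.normal(0, s_p, L)
        p_new = expit(z_new)
        ll_new = _betabin_loglik(alt, genes, p_new, alpha * delta, beta)
        logr = (ll_new - ll).sum(axis=1) + np.log(p_new * (1 - p_new)) - np.log(
            p * (1 - p)
        )
        acc = np.log(rng.random(L)) < logr
        p = np.where(acc, p_new, p)
        ll[acc] = ll_new[acc]
        if adapt_acc is not None:
            adapt_acc["p"] += acc
        # alpha_i where included
        a_new = alpha + rng.normal(0, s_a, L)
        ll_new = _betabin_loglik(alt, genes, p, a_new * delta, beta)
        logr = (ll_new - ll).sum(axis=1) + (alpha**2 - a_new**2) / (
            2 * sd_alpha_prior**2
        )
        acc = delta & (np.log(rng.random(L)) < logr)
        alpha = np.where(acc, a_new, alpha)
        ll[acc] = ll_new[acc]
        if adapt_acc is not None:
            adapt_acc["a"] += acc
        # reversible jump on delta_i (alpha proposed from its prior)
        a_prop = rng.normal(0, sd_alpha_prior, L)
        delta_new = ~delta
        alpha_new = np.where(delta_new, np.where(delta, alpha, a_prop), alpha)
        ll_new = _betabin_loglik(alt, genes, p, alpha_new * delta_new, beta)
        log_prior_odds = np.where(
            delta_new, np.log(pi_incl / (1 - pi_incl)), np.log((1 - pi_incl) / pi_incl)
        )
        logr = (ll_new - ll).sum(axis=1) + log_prior_odds
        acc = np.log(rng.random(L)) < logr
        delta = np.where(acc, delta_new, delta)
        alpha = np.where(acc & delta, alpha_new, np.where(acc & ~delta, 0.0, alpha))
        ll[acc] = ll_new[acc]
        # beta_j
        for j in range(P):
            b_new = beta.copy()
            b_new[j] = beta[j] + rng.normal(0, s_b[j])
            ll_new_col = _betabin_loglik(
                alt[:, j : j + 1], genes[:, j : j + 1], p, alpha * delta,
                b_new[j : j + 1],
            )
            logr = (ll_new_col - ll[:, j : j + 1]).sum() + (
                (beta[j] - beta_mu) ** 2 - (b_new[j] - beta_mu) ** 2
            ) / (2 * beta_sd**2)
            if np.log(rng.random()) < logr:
                beta = b_new
                ll[:, j] = ll_new_col[:, 0]
                if adapt_acc is not None:
                    adapt_acc["b"][j] += 1

    # pilot adaptation
    final_rates = {}
    for _ in range(n_pilot):
        acc = {"p": np.zeros(L), "a": np.zeros(L), "b": np.zeros(P)}
        n_incl = np.zeros(L)
        for _ in range(pilot_len):
            sweep(acc)
            n_incl += delta
        rate_p = acc["p"] / pilot_len
        rate_a = acc["a"] / np.maximum(n_incl, 1)
        rate_b = acc["b"] / pilot_len
        for s, rate in ((s_p, rate_p), (s_a, rate_a), (s_b, rate_b)):
            s *= np.where(rate > 0.45, 1.5, np.where(rate < 0.25, 1 / 1.5, 1.0))
            np.clip(s, 1e-3, 10.0, out=s)
        final_rates = {"p": rate_p.mean(), "a": rate_a[n_incl > 0].mean()
                       if (n_incl > 0).any() else np.nan, "b": rate_b.mean()}
    if final_rates and not (
        0.1 <= final_rates["p"] <= 0.6 and 0.1 <= final_rates["b"] <= 0.6
    ):
        warnings.warn(f"pilot acceptance outside [0.1, 0.6]: {final_rates}")

    for _ in range(burnin):
        sweep()

    incl = np.zeros(L)
    alpha_sum = np.zeros(L)
    alpha_n = np.zeros(L)
    fst_sum = np.zeros(L)
    for _ in range(n_iter):
        for _ in range(thin):
            sweep()
        incl += delta
        alpha_sum += np.where(delta, alpha, 0.0)
        alpha_n += delta
        fst_sum += expit(alpha * delta + beta.mean())
    post_prob = incl / n_iter
    alpha_mean = np.where(alpha_n > 0, alpha_sum / np.maximum(alpha_n, 1), 0.0)
    fst_mean = fst_sum / n_iter

    order = np.argsort(-post_prob, kind="stable")
    qvals = np.empty(L)
    qvals[order] = np.cumsum(1.0 - post_prob[order]) / np.arange(1, L + 1)
    flagged_mask = (qvals < q_threshold) & (alpha_mean > 0)
    table = pd.DataFrame(
        {
            "locus": m.locus_ids,
            "fst": fst_mean,
            "alpha": alpha_mean,
            "post_prob_selection": post_prob,
            "q_value": qvals,
            "flag": flagged_mask,
        }
    ).set_index("locus")
    return OutlierResult(
        scan="bayescan",
        table=table,
        flagged=set(np.asarray(m.locus_ids)[flagged_mask]),
        diagnostics={"pilot_acceptance": final_rates, "prior_odds": prior_odds},
    )


# ---------------------------------------------------------------------------
# FDIST-style scan


def fdist_scan(
    m: SNPMatrix,
    pmap: PopulationMap,
    n_sims: int = 20000,
    n_demes: int = 100,
    fdr: float = 0.01,
    rng=None,
) -> OutlierResult:
    """Finite-island null-simulation scan.

    The island model uses ``n_demes`` demes per sampled population with the
    sampled populations occupying one deme each, migration tuned so the
    expected FST matches the observed multilocus global FST.  Per-locus
    p-values are one-sided (high-FST) ranks within heterozygosity bins
    (50 equal-count bins, neighbours pooled below 100 null points), adjusted
    by Benjamini-Hochberg at ``fdr``.
    """
    rng = _as_rng(rng)
    alt, genes, pops = _pop_allele_counts(m, pmap)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    fst_obs, he_obs = _anova_fst(alt, genes)
    usable = np.isfinite(fst_obs)
    # multilocus global FST: ratio of summed variance components
    global_fst = _global_fst(alt[usable], genes[usable])
    if not np.isfinite(global_fst) or global_fst <= 0:
        raise ValueError("target FST non-positive; island null unattainable")

    P = len(pops)
    D = n_demes * P
    a = (D / (D - 1.0)) ** 2
    M = (1.0 / global_fst - 1.0) / a          # 4Nm
    scaled_mig = M / 2.0                      # per-lineage rate in 2N units
    # sampled populations occupy one deme each, spread across the island
    sizes = np.round(genes.mean(axis=0) / 2).astype(np.int64)  # diploids per pop
    gene_deme = np.repeat(np.arange(P, dtype=np.int64) * n_demes, 2 * sizes)
    derived = _kernel.simulate_island_loci(
        n_sims, gene_deme, D, scaled_mig, int(rng.integers(2**31 - 1))
    )
    onehot = np.zeros((len(gene_deme), P))
    onehot[np.arange(len(gene_deme)), gene_deme // n_demes] = 1.0
    null_alt = derived.astype(np.float64) @ onehot
    null_genes = np.broadcast_to(onehot.sum(axis=0), null_alt.shape)
    fst_null, he_null = _anova_fst(null_alt, null_genes)
    ok = np.isfinite(fst_null)
    fst_null, he_null = fst_null[ok], he_null[ok]

    # heterozygosity-conditioned p-values
    n_bins = 50
    edges = np.quantile(he_null, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_null = np.clip(np.searchsorted(edges, he_null, side="right") - 1, 0, n_bins - 1)
    pvals = np.full(m.n_loci, np.nan)
    idx_usable = np.flatnonzero(usable)
    bin_obs = np.clip(
        np.searchsorted(edges, he_obs[usable], side="right") - 1, 0, n_bins - 1
    )
    for b in np.unique(bin_obs):
        lo = hi = b
        sel = bin_null == b
        while sel.sum() < 100 and (lo > 0 or hi < n_bins - 1):
            lo, hi = max(lo - 1, 0), min(hi + 1, n_bins - 1)
            sel = (bin_null >= lo) & (bin_null <= hi)
        ref = np.sort(fst_null[sel])
        here = bin_obs == b
        ge = len(ref) - np.searchsorted(ref, fst_obs[usable][here], side="left")
        pvals[idx_usable[here]] = (ge + 1.0) / (len(ref) + 1.0)

    from statsmodels.stats.multitest import multipletests

    padj = np.full(m.n_loci, np.nan)
    fin = np.isfinite(pvals)
    if fin.any():
        rej, adj, _, _ = multipletests(pvals[fin], alpha=fdr, method="fdr_bh")
        padj[fin] = adj
        flag = np.zeros(m.n_loci, dtype=bool)
        flag[fin] = rej
    else:
        flag = np.zeros(m.n_loci, dtype=bool)
    table = pd.DataFrame(
        {
            "locus": m.locus_ids,
            "fst": fst_obs,
            "heterozygosity": he_obs,
            "p_value": pvals,
            "p_adjusted": padj,
            "flag": flag,
        }
    ).set_index("locus")
    return OutlierResult(
        scan="fdist",
        table=table,
        flagged=set(np.asarray(m.locus_ids)[flag]),
        diagnostics={
            "global_fst": float(global_fst),
            "null_fst_mean": float(fst_null.mean()),
            "null_global_fst": _global_fst(
                null_alt[ok], np.asarray(null_genes)[ok]
            ),
            "n_null": int(len(fst_null)),
            "scaled_migration": float(scaled_mig),
        },
    )


def _global_fst(alt, genes):
    """Multilocus ANOVA FST: ratio of summed components across loci."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(genes > 0, alt / np.maximum(genes, 1), np.nan)
    N = genes.sum(axis=1)
    r = (genes > 0).sum(axis=1)
    pbar = alt.sum(axis=1) / N
    with np.errstate(invalid="ignore", divide="ignore"):
        ssa = np.nansum(genes * (p - pbar[:, None]) ** 2, axis=1)
        ssw = np.nansum(genes * p * (1 - p), axis=1)
        msw = ssw / np.maximum(N - r, 1)
        msa = ssa / np.maximum(r - 1, 1)
        nc = (N - (genes**2).sum(axis=1) / N) / np.maximum(r - 1, 1)
        sa = (msa - msw) / nc
    good = np.isfinite(sa) & np.isfinite(msw)
    denom = (sa + msw)[good].sum()
    return float(sa[good].sum() / denom) if denom > 0 else np.nan


def intersect_outliers(a: OutlierResult, b: OutlierResult) -> set[str]:
    """Loci flagged by both scans."""
    return set(a.flagged) & set(b.flagged)
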