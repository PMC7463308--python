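"""Per-population diversity, pairwise PhiST, hierarchical AMOVA, and
diversity-geography regressions.

AMOVA follows the classical sums-of-squared-deviations (SSD) decomposition on
inter-individual distances, here the allele mismatch count between diploid
genotypes at a SNP (|g_i - g_j| for copy numbers 0/1/2).  For a set of
individuals with genotype counts (n0, n1, n2) the pair sum has the closed form
n0*n1 + n1*n2 + 2*n0*n2, so all SSD terms reduce to per-(population, locus)
genotype counts and the whole decomposition vectorizes over loci.  Missing
genotypes are dropped pairwise per locus; SSDs, degrees of freedom, and the
moment-estimator coefficients are summed over loci before variance components
are formed.  Negative components are reported as computed (flagged, not
truncated).

Significance is assessed by permutation: individuals among populations for
Phi_ST, individuals among populations within groups for Phi_SC, and whole
populations among groups for Phi_CT, with p = (#{perm >= obs} + 1)/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, PopulationMap, SNPMatrix

__all__ = [
    "DiversityResult",
    "AmovaResult",
    "diversity",
    "pairwise_phist",
    "amova",
    "diversity_gradient",
]


@dataclass
class DiversityResult:
    """Per-population diversity table (pi, Hexp, Hobs, n_samples)."""

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


@dataclass
class AmovaResult:
    levels: int
    sigma2: dict[str, float]
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    df: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def percent_variance(self) -> dict[str, float]:
        total = sum(self.sigma2.values())
        if total == 0:
            return {k: 0.0 for k in self.sigma2}
        return {k: 100.0 * v / total for k, v in self.sigma2.items()}


# ---------------------------------------------------------------------------
# Diversity


def diversity(m: SNPMatrix, pmap: PopulationMap, min_n: int = 5) -> DiversityResult:
    """Unbiased per-population diversity with pairwise deletion.

    Per locus with sample alternate-allele frequency p over n observed genes,
    gene diversity is 2p(1-p) * n/(n-1).  ``pi`` averages this over all loci
    observed in the population; ``hexp``/``hobs`` average gene diversity and
    the heterozygote fraction over loci *polymorphic within the population*.
    Populations with fewer than ``min_n`` samples are excluded with a warning.
    """
    rows = []
    excluded = []
    for pop, idx in pmap.pop_indices(m).items():
        if len(idx) < min_n:
            excluded.append(pop)
            continue
        g = m.genotypes[idx]
        obs = g != MISSING
        n_genes = 2 * obs.sum(axis=0)
        alt = np.where(obs, g, 0).sum(axis=0)
        seen = n_genes >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n_genes
            h = 2.0 * p * (1.0 - p) * n_genes / (n_genes - 1.0)
        h = np.where(seen, h, np.nan)
        poly = seen & (alt > 0) & (alt < n_genes)
        pi = float(np.nanmean(h)) if seen.any() else 0.0
        if poly.any():
            hexp = float(np.mean(h[poly]))
            het = (g == 1)[:, poly].sum(axis=0) / obs[:, poly].sum(axis=0)
            hobs = float(np.mean(het))
        else:
            hexp = hobs = 0.0
        rows.append({"population": pop, "pi": pi, "hexp": hexp, "hobs": hobs,
                     "n_samples": len(idx)})
    if excluded:
        warnings.warn(
            f"populations below min_n={min_n} excluded: {sorted(excluded)}"
        )
    table = pd.DataFrame(rows).set_index("population") if rows else pd.DataFrame(
        columns=["pi", "hexp", "hobs", "n_samples"]
    )
    return DiversityResult(table=table, excluded=excluded)


# ---------------------------------------------------------------------------
# AMOVA machinery (count based)


def _genotype_counts(geno: np.ndarray, members: np.ndarray) -> np.ndarray:
    """counts[k, p, l] = number of individuals with genotype k in unit p at locus l.

    ``members`` is a (n_units, n_individuals) 0/1 matrix.
    """
    out = np.empty((3, members.shape[0], geno.shape[1]))
    for k in range(3):
        out[k] = members @ (geno == k)
    return out


def _pair_sum(counts: np.ndarray) -> np.ndarray:
    """Sum of allele mismatch distances over unordered pairs, from counts."""
    n0, n1, n2 = counts[0], counts[1], counts[2]
    return n0 * n1 + n1 * n2 + 2.0 * n0 * n2


def _ss_terms(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(SS, n) per unit per locus; SS = pair sum / n (0 where empty)."""
    n = counts.sum(axis=0)
    s = _pair_sum(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(n > 0, s / np.maximum(n, 1), 0.0)
    return ss, n


def _amova_components(pop_counts: np.ndarray, pop_group: np.ndarray, levels: int):
    """Variance components from per-(population, locus) genotype counts.

    ``pop_counts``: (3, P, L); ``pop_group``: group index per population.
    Returns (sigma2 dict, df dict, flags).
    """
    flags: list[str] = []
    ss_p, n_p = _ss_terms(pop_counts)            # (P, L)
    n_groups = int(pop_group.max()) + 1 if len(pop_group) else 0
    gmat = np.zeros((n_groups, pop_counts.shape[1]))
    gmat[pop_group, np.arange(pop_counts.shape[1])] = 1.0
    grp_counts = np.einsum("gp,kpl->kgl", gmat, pop_counts)
    ss_g, n_g = _ss_terms(grp_counts)            # (G, L)
    tot_counts = pop_counts.sum(axis=1)          # (3, L)
    ss_t, n_t = _ss_terms(tot_counts[:, None, :])
    ss_t, n_t = ss_t[0], n_t[0]                  # (L,)

    present_p = n_p > 0
    present_g = n_g > 0
    P_l = present_p.sum(axis=0)
    G_l = present_g.sum(axis=0)

    ssd_wp = ss_p.sum(axis=0)
    ssd_ag = ss_t - ss_g.sum(axis=0)
    ssd_ap = ss_g.sum(axis=0) - ssd_wp

    df_wp = (n_t - P_l).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_np2_over_ng = np.where(
            n_g > 0, np.einsum("gp,pl->gl", gmat, n_p**2) / np.maximum(n_g, 1), 0.0
        ).sum(axis=0)                            # B_l
        C_l = (n_p**2).sum(axis=0) / np.maximum(n_t, 1)
        D_l = (n_g**2).sum(axis=0) / np.maximum(n_t, 1)

    if df_wp <= 0:
        flags.append("degenerate:no-within-df")
        sig_c = 0.0
    else:
        sig_c = float(ssd_wp.sum() / df_wp)

    if levels == 2:
        df_ap = (P_l - 1).sum()
        ssd_among = ssd_ap + ssd_ag              # total among-population SSD
        coef = (n_t - C_l).sum()
        if df_ap <= 0 or coef <= 0:
            flags.append("degenerate:single-population")
            sig_a = 0.0
        else:
            sig_a = float((ssd_among.sum() - df_ap * sig_c) / coef)
        sigma2 = {"among_populations": sig_a, "within_populations": sig_c}
        df = {"among_populations": float(df_ap), "within_populations": float(df_wp)}
        return sigma2, df, flags

    df_ap = (P_l - G_l).sum()
    df_ag = (G_l - 1).sum()
    coef_b = (n_t - sum_np2_over_ng).sum()
    if df_ap <= 0 or coef_b <= 0:
        flags.append("degenerate:one-population-per-group")
        sig_b = 0.0
    else:
        sig_b = float((ssd_ap.sum() - df_ap * sig_c) / coef_b)
    coef_b_ag = (sum_np2_over_ng - C_l).sum()
    coef_a = (n_t - D_l).sum()
    if df_ag <= 0 or coef_a <= 0:
        flags.append("degenerate:single-group")
        sig_a = 0.0
    else:
        sig_a = float(
            (ssd_ag.sum() - df_ag * sig_c - coef_b_ag * sig_b) / coef_a
        )
    sigma2 = {
        "among_groups": sig_a,
        "among_populations_within_groups": sig_b,
        "within_populations": sig_c,
    }
    df = {
        "among_groups": float(df_ag),
        "among_populations_within_groups": float(df_ap),
        "within_populations": float(df_wp),
    }
    return sigma2, df, flags


def _phi_from_sigma2(sigma2: dict[str, float], levels: int):
    if levels == 2:
        a, c = sigma2["among_populations"], sigma2["within_populations"]
        tot = a + c
        phi_st = a / tot if tot != 0 else 0.0
        return phi_st, None, None
    a = sigma2["among_groups"]
    b = sigma2["among_populations_within_groups"]
    c = sigma2["within_populations"]
    tot = a + b + c
    phi_st = (a + b) / tot if tot != 0 else 0.0
    phi_ct = a / tot if tot != 0 else 0.0
    phi_sc = b / (b + c) if (b + c) != 0 else 0.0
    return phi_st, phi_sc, phi_ct


def _members_matrix(pop_of_row: np.ndarray, n_pops: int) -> np.ndarray:
    mem = np.zeros((n_pops, len(pop_of_row)))
    mem[pop_of_row, np.arange(len(pop_of_row))] = 1.0
    return mem


def _pop_layout(m: SNPMatrix, pmap: PopulationMap):
    pops = [p for p in pmap.populations if p in set(pmap.sample_to_pop[s] for s in m.sample_ids)]
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_of_row = np.array(
        [pop_index[pmap.sample_to_pop[s]] for s in m.sample_ids], dtype=np.int64
    )
    groups = list(dict.fromkeys(pmap.pop_to_group[p] for p in pops))
    grp_index = {g: i for i, g in enumerate(groups)}
    pop_group = np.array([grp_index[pmap.pop_to_group[p]] for p in pops], dtype=np.int64)
    return pops, pop_of_row, pop_group


def amova(
    m: SNPMatrix,
    pmap: PopulationMap,
    levels: int = 3,
    n_perm: int = 10000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA over all loci with permutation tests.

    ``levels=2`` partitions variance among/within populations (Phi_ST only);
    ``levels=3`` adds the among-group level (Phi_CT, Phi_SC).
    """
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    pops, pop_of_row, pop_group = _pop_layout(m, pmap)
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if levels == 3 and len(set(pop_group)) < 2:
        raise ValueError("3-level AMOVA needs at least 2 groups")
    geno = m.genotypes
    counts = _genotype_counts(geno, _members_matrix(pop_of_row, len(pops)))
    sigma2, df, flags = _amova_components(counts, pop_group, levels)
    phi_st, phi_sc, phi_ct = _phi_from_sigma2(sigma2, levels)

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_values = _permutation_pvalues(
            geno, pop_of_row, pop_group, levels, (phi_st, phi_sc, phi_ct),
            n_perm, rng,
        )
    return AmovaResult(
        levels=levels, sigma2=sigma2, phi_st=phi_st, phi_sc=phi_sc,
        phi_ct=phi_ct, df=df, p_values=p_values, flags=flags,
    )


def _phis_for(geno, pop_of_row, pop_group, levels):
    counts = _genotype_counts(
        geno, _members_matrix(pop_of_row, int(pop_group.shape[0]))
    )
    sigma2, _, _ = _amova_components(counts, pop_group, levels)
    return _phi_from_sigma2(sigma2, levels)


def _permutation_pvalues(geno, pop_of_row, pop_group, levels, observed, n_perm, rng):
    phi_st_obs, phi_sc_obs, phi_ct_obs = observed
    n_pops = int(pop_group.shape[0])
    ge_st = ge_sc = ge_ct = 0
    for _ in range(n_perm):
        # Phi_ST: individuals among populations
        perm_rows = rng.permutation(pop_of_row)
        st, _, _ = _phis_for(geno, perm_rows, pop_group, levels)
        ge_st += st >= phi_st_obs
        if levels == 3:
            # Phi_SC: individuals among populations within groups
            perm_within = pop_of_row.copy()
            grp_of_row = pop_group[pop_of_row]
            for g in np.unique(pop_group):
                rows = np.flatnonzero(grp_of_row == g)
                perm_within[rows] = perm_within[rows[rng.permutation(len(rows))]]
            _, sc, _ = _phis_for(geno, perm_within, pop_group, levels)
            ge_sc += sc >= phi_sc_obs
            # Phi_CT: whole populations among groups
            perm_groups = pop_group[rng.permutation(n_pops)]
            _, _, ct = _phis_for(geno, pop_of_row, perm_groups, levels)
            ge_ct += ct >= phi_ct_obs
    out = {"phi_st": (ge_st + 1) / (n_perm + 1)}
    if levels == 3:
        out["phi_sc"] = (ge_sc + 1) / (n_perm + 1)
        out["phi_ct"] = (ge_ct + 1) / (n_perm + 1)
    return out


def pairwise_phist(m: SNPMatrix, pmap: PopulationMap) -> pd.DataFrame:
    """Symmetric population x population Phi_ST matrix (2-level AMOVA per pair).

    Negative estimates are reported as computed; clamp only when a
    dissimilarity response in [0, 1) is required downstream.
    """
    pops, pop_of_row, _ = _pop_layout(m, pmap)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    geno = m.genotypes
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            rows = np.flatnonzero(np.isin(pop_of_row, (i, j)))
            sub = geno[rows]
            shared = ((sub != MISSING).sum(axis=0) > 0)
            if not shared.any():
                raise ValueError(
                    f"populations {pops[i]!r},{pops[j]!r} share no genotyped loci"
                )
            sub_pop = (pop_of_row[rows] == j).astype(np.int64)
            counts = _genotype_counts(sub, _members_matrix(sub_pop, 2))
            sigma2, _, _ = _amova_components(counts, np.array([0, 1]), 2)
            phi, _, _ = _phi_from_sigma2(sigma2, 2)
            out.iloc[i, j] = out.iloc[j, i] = phi
    return out


# ---------------------------------------------------------------------------
# Diversity ~ geography


def diversity_gradient(values, coords, axis: str = "lat"):
    """Pearson r and two-sided p of per-population diversity against lat or lon.

    ``values``: mapping population -> diversity value; ``coords``: mapping
    population -> (lat, lon).  Returns (r, p); a zero-variance response is
    degenerate and reported as r = 0, p = 1.
    """
    pops = [p for p in values if p in coords]
    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    y = np.array([values[p] for p in pops], dtype=float)
    k = {"lat": 0, "lon": 1}[axis]
    x = np.array([coords[p][k] for p in pops], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"zero variance in {axis}")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
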