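"""Event-driven coalescent kernels (numba-jitted).

Two samplers share the same single-SNP mutation model: one independent
genealogy per locus, one mutation placed uniformly on total branch length.
Because every genealogy fully coalesces, the derived allele is automatically
polymorphic in the pooled sample (the single-SNP-per-locus conditioning).

``simulate_scenario_loci`` handles piecewise-constant population sizes with
scheduled backward-in-time events (merges, instantaneous size changes,
admixture splits).  ``simulate_island_loci`` is a finite-island structured
coalescent in time units of 2N generations, used to build the FDIST null.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event type codes for simulate_scenario_loci
EV_MERGE = 0      # all lineages in pop a join pop b; param > 0 resizes b
EV_RESIZE = 1     # pop a gets diploid size param
EV_ADMIX = 2      # lineages in pop a go to pop b with prob param, else pop c


@njit(cache=True)
def _place_mutation(n_genes, n_nodes, node_time, parent, child1, child2, derived_row):
    """Pick a branch with probability proportional to length; mark tip descendants."""
    total = 0.0
    for v in range(n_nodes - 1):  # root (last created node) excluded
        total += node_time[parent[v]] - node_time[v]
    u = np.random.random() * total
    acc = 0.0
    vm = 0
    for v in range(n_nodes - 1):
        acc += node_time[parent[v]] - node_time[v]
        if acc >= u:
            vm = v
            break
    # collect sample tips below vm
    stack = np.empty(n_nodes, np.int64)
    stack[0] = vm
    top = 1
    while top > 0:
        top -= 1
        v = stack[top]
        if v < n_genes:
            derived_row[v] = 1
        else:
            stack[top] = child1[v]
            stack[top + 1] = child2[v]
            top += 2


@njit(cache=True)
def simulate_scenario_loci(
    n_loci, gene_pop, n_pops, sizes0, ev_time, ev_type, ev_a, ev_b, ev_c,
    ev_param, seed,
):
    """Derived-allele masks (n_loci x n_genes, uint8) under a scenario.

    ``gene_pop``: initial population index per sampled gene; ``sizes0``:
    diploid sizes at sampling time; events sorted ascending in time (ties keep
    array order).  Pair-coalescence rate within a population of diploid size N
    is 1/(2N) per generation.
    """
    n_genes = gene_pop.shape[0]
    n_nodes = 2 * n_genes - 1
    out = np.zeros((n_loci, n_genes), np.uint8)
    np.random.seed(seed)
    n_ev = ev_time.shape[0]

    node_time = np.empty(n_nodes)
    parent = np.empty(n_nodes, np.int64)
    child1 = np.empty(n_nodes, np.int64)
    child2 = np.empty(n_nodes, np.int64)
    members = np.empty((n_pops, n_genes), np.int64)
    k = np.empty(n_pops, np.int64)
    sizes = np.empty(n_pops)
    rates = np.empty(n_pops)

    for locus in range(n_loci):
        for p in range(n_pops):
            k[p] = 0
            sizes[p] = sizes0[p]
        for g in range(n_genes):
            p = gene_pop[g]
            members[p, k[p]] = g
            k[p] += 1
            node_time[g] = 0.0
        parent[:] = -1
        t = 0.0
        iev = 0
        n_active = n_genes
        nxt = n_genes
        while n_active > 1:
            rate_tot = 0.0
            for p in range(n_pops):
                r = k[p] * (k[p] - 1) / (4.0 * sizes[p])
                rates[p] = r
                rate_tot += r
            t_ev = ev_time[iev] if iev < n_ev else np.inf
            if rate_tot > 0.0:
                wait = np.random.exponential(1.0 / rate_tot)
            else:
                wait = np.inf
            if t + wait < t_ev:
                t += wait
                u = np.random.random() * rate_tot
                p = 0
                acc = rates[0]
                while acc < u and p < n_pops - 1:
                    p += 1
                    acc += rates[p]
                kp = k[p]
                i = np.random.randint(kp)
                j = np.random.randint(kp - 1)
                if j >= i:
                    j += 1
                a = members[p, i]
                b = members[p, j]
                node_time[nxt] = t
                child1[nxt] = a
                child2[nxt] = b
                parent[a] = nxt
                parent[b] = nxt
                lo = i if i < j else j
                hi = j if i < j else i
                members[p, lo] = nxt
                members[p, hi] = members[p, kp - 1]
                k[p] = kp - 1
                nxt += 1
                n_active -= 1
            elif iev < n_ev:
                t = t_ev
                typ = ev_type[iev]
                a = ev_a[iev]
                if typ == EV_MERGE:
                    b = ev_b[iev]
                    for m in range(k[a]):
                        members[b, k[b]] = members[a, m]
                        k[b] += 1
                    k[a] = 0
                    if ev_param[iev] > 0.0:
                        sizes[b] = ev_param[iev]
                elif typ == EV_RESIZE:
                    sizes[a] = ev_param[iev]
                else:  # EV_ADMIX
                    b = ev_b[iev]
                    c = ev_c[iev]
                    for m in range(k[a]):
                        lin = members[a, m]
                        if np.random.random() < ev_param[iev]:
                            members[b, k[b]] = lin
                            k[b] += 1
                        else:
                            members[c, k[c]] = lin
                            k[c] += 1
                    k[a] = 0
                iev += 1
            else:
                # lineages stranded in isolated populations: invalid scenario
                return np.zeros((0, 0), np.uint8)
        _place_mutation(n_genes, nxt, node_time, parent, child1, child2, out[locus])
    return out


@njit(cache=True)
def simulate_island_loci(n_loci, gene_deme, n_demes, scaled_mig, seed):
    """Derived masks under a finite-island coalescent (time units of 2N gens).

    Pair-coalescence rate within a deme is 1; each lineage migrates to a
    uniformly chosen other deme at rate ``scaled_mig`` (= 2Nm).
    """
    n_genes = gene_deme.shape[0]
    n_nodes = 2 * n_genes - 1
    out = np.zeros((n_loci, n_genes), np.uint8)
    np.random.seed(seed)

    node_time = np.empty(n_nodes)
    parent = np.empty(n_nodes, np.int64)
    child1 = np.empty(n_nodes, np.int64)
    child2 = np.empty(n_nodes, np.int64)
    lin_node = np.empty(n_genes, np.int64)   # active lineage -> node id
    lin_deme = np.empty(n_genes, np.int64)
    k_of = np.zeros(n_demes, np.int64)

    for locus in range(n_loci):
        for d in range(n_demes):
            k_of[d] = 0
        for g in range(n_genes):
            lin_node[g] = g
            lin_deme[g] = gene_deme[g]
            k_of[gene_deme[g]] += 1
            node_time[g] = 0.0
        parent[:] = -1
        pair_sum = 0.0
        for d in range(n_demes):
            pair_sum += k_of[d] * (k_of[d] - 1) / 2.0
        n_active = n_genes
        t = 0.0
        nxt = n_genes
        while n_active > 1:
            mig_tot = n_active * scaled_mig
            rate_tot = pair_sum + mig_tot
            t += np.random.exponential(1.0 / rate_tot)
            if np.random.random() * rate_tot < pair_sum:
                # coalescence: choose deme with prob k(k-1)/2
                u = np.random.random() * pair_sum
                acc = 0.0
                dsel = 0
                for d in range(n_demes):
                    acc += k_of[d] * (k_of[d] - 1) / 2.0
                    if acc >= u:
                        dsel = d
                        break
                # pick two lineages in dsel
                i1 = np.random.randint(k_of[dsel])
                i2 = np.random.randint(k_of[dsel] - 1)
                if i2 >= i1:
                    i2 += 1
                seen = 0
                a_idx = -1
                b_idx = -1
                for m in range(n_active):
                    if lin_deme[m] == dsel:
                        if seen == i1:
                            a_idx = m
                        if seen == i2:
                            b_idx = m
                        seen += 1
                a = lin_node[a_idx]
                b = lin_node[b_idx]
                node_time[nxt] = t
                child1[nxt] = a
                child2[nxt] = b
                parent[a] = nxt
                parent[b] = nxt
                lo = a_idx if a_idx < b_idx else b_idx
                hi = b_idx if a_idx < b_idx else a_idx
                lin_node[lo] = nxt
                lin_deme[lo] = dsel
                lin_node[hi] = lin_node[n_active - 1]
                lin_deme[hi] = lin_deme[n_active - 1]
                n_active -= 1
                pair_sum -= (k_of[dsel] - 1)
                k_of[dsel] -= 1
                nxt += 1
            else:
                # migration
                m = np.random.randint(n_active)
                src = lin_deme[m]
                dst = np.random.randint(n_demes - 1)
                if dst >= src:
                    dst += 1
                pair_sum -= (k_of[src] - 1)
                k_of[src] -= 1
                pair_sum += k_of[dst]
                k_of[dst] += 1
                lin_deme[m] = dst
        _place_mutation(n_genes, nxt, node_time, parent, child1, child2, out[locus])
    return out
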