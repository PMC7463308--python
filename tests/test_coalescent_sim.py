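"""Coalescent SNP simulator against a naive pure-Python oracle and its
analytic limits."""

import numpy as np
import pytest
from scipy import stats

from relictgen.coalescent_sim import (
    ParameterDraw,
    ScenarioSpec,
    builtin_scenarios,
    sample_prior,
    simulate_group_counts,
    simulate_snps,
)
from relictgen.popgen_stats import amova

from conftest import make_popmap


# ---------------------------------------------------------------------------
# Oracle: naive O(n^2) single-population coalescent with one mutation placed
# uniformly on total branch length (independent of the jitted kernel).


def naive_panmictic_derived_counts(n_genes, N, n_loci, rng):
    out = np.empty(n_loci, dtype=int)
    for l in range(n_loci):
        lineages = [(1, 0.0)] * n_genes  # (descendant tip count, birth time)
        t = 0.0
        spans = []  # (desc count, branch length)
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(4.0 * N / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            (ci, ti), (cj, tj) = lineages[i], lineages[j]
            spans.append((ci, t - ti))
            spans.append((cj, t - tj))
            lineages = [lineages[m] for m in range(k) if m not in (i, j)]
            lineages.append((ci + cj, t))
        total = sum(s for _, s in spans)
        u = rng.uniform(0, total)
        acc = 0.0
        for c, s in spans:
            acc += s
            if acc >= u:
                out[l] = c
                break
    return out


def _panmictic_spec(n_diploids, N):
    return ScenarioSpec(
        name="single", groups=["POP"], sample_sizes={"POP": n_diploids},
        initial_sizes={"POP": float(N)}, events=[], priors={}, constraints=[],
    )


class TestKernelAgainstOracle:
    def test_derived_count_distribution_matches_naive_coalescent(self):
        """Folded site-frequency spectrum and mean heterozygosity agree with
        the independently coded O(n^2) oracle within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        n_genes, n_loci = 10, 2000
        oracle_counts = naive_panmictic_derived_counts(n_genes, 1000.0, n_loci,
                                                       rng)
        spec = _panmictic_spec(n_genes // 2, 1000.0)
        draw = ParameterDraw("single", {})
        counts, sizes = simulate_group_counts(spec, draw, n_loci, rng)
        kernel_counts = counts[0].astype(int)
        assert sizes[0] == n_genes
        # mean sample heterozygosity 2c(n-c)/(n(n-1)) per locus
        def het(c):
            return 2.0 * c * (n_genes - c) / (n_genes * (n_genes - 1))

        h_o, h_k = het(oracle_counts.astype(float)), het(kernel_counts.astype(float))
        se = np.sqrt(h_o.var() / n_loci + h_k.var() / n_loci)
        assert abs(h_o.mean() - h_k.mean()) < 3 * se
        # two-sample test on the derived-count distributions
        p = stats.ks_2samp(oracle_counts, kernel_counts).pvalue
        assert p > 0.001

    def test_all_loci_polymorphic_in_pooled_sample(self):
        rng = np.random.default_rng(1)
        m, _ = simulate_snps(_panmictic_spec(8, 500.0), ParameterDraw("s", {}),
                             300, rng)
        alt, n = m.allele_counts()
        assert (alt > 0).all() and (alt < n).all()


class TestScenarioLimits:
    def _two_pop_spec(self, t_split, N=1000.0):
        return ScenarioSpec(
            name="pair", groups=["A", "B"],
            sample_sizes={"A": 10, "B": 10},
            initial_sizes={"A": N, "B": N},
            events=[{"time": t_split, "type": "merge", "source": "B",
                     "dest": "A"}],
            priors={}, constraints=[],
        )

    def test_split_time_zero_is_panmixia(self):
        rng = np.random.default_rng(2)
        m, pmap = simulate_snps(self._two_pop_spec(1e-9), ParameterDraw("p", {}),
                                1000, rng)
        res = amova(m, pmap, levels=2, n_perm=0)
        assert abs(res.phi_st) < 0.02

    def test_deep_divergence_high_phist(self):
        rng = np.random.default_rng(3)
        m, pmap = simulate_snps(self._two_pop_spec(5e4), ParameterDraw("p", {}),
                                1000, rng)
        res = amova(m, pmap, levels=2, n_perm=0)
        assert res.phi_st > 0.9

    def test_s2_with_equal_split_times_matches_s1(self):
        """As t2 -> t1 the two-stage split degenerates to a simultaneous
        three-way split: summary distributions indistinguishable."""
        from relictgen.abc import summarize_counts

        scen = builtin_scenarios()["divergence"]
        vals = {"N_A": 5e4, "N_SW": 4e4, "N_CE": 6e4, "N_JP": 4e4,
                "t1": 2e5, "t2": 2e5 - 1e-6}
        rng = np.random.default_rng(4)
        rows = {name: [] for name in ("S1", "S2")}
        for name in rows:
            spec = scen[name]
            draw = ParameterDraw(name, {k: vals[k] for k in spec.priors})
            for _ in range(300):
                c, s = simulate_group_counts(spec, draw, 60, rng)
                rows[name].append(summarize_counts(c, s, spec.groups).values)
        a, b = (np.vstack(rows[k]) for k in ("S1", "S2"))
        for col in (0, 9, 12):  # monomorphic and FST summaries
            assert stats.ks_2samp(a[:, col], b[:, col]).pvalue > 0.01

    def test_full_admixture_collapses_to_two_stage_split(self):
        """ra = 1 sends every admixed lineage to the SW side: statistics match
        the S2 topology with the same parameters."""
        from relictgen.abc import summarize_counts

        scen = builtin_scenarios()["divergence"]
        vals = {"N_A": 5e4, "N_SW": 4e4, "N_CE": 6e4, "N_JP": 4e4,
                "t1": 4e5, "t2": 1e5, "ra": 1.0}
        rng = np.random.default_rng(5)
        rows = {}
        for name in ("S2", "S5"):
            spec = scen[name]
            draw = ParameterDraw(name, {k: vals[k] for k in spec.priors})
            rows[name] = np.vstack([
                summarize_counts(*simulate_group_counts(spec, draw, 60, rng),
                                 spec.groups).values
                for _ in range(300)
            ])
        for col in (9, 12, 15):  # the three pairwise FST summaries
            assert stats.ks_2samp(rows["S2"][:, col],
                                  rows["S5"][:, col]).pvalue > 0.01


class TestPriors:
    def test_draws_respect_bounds_and_constraints(self):
        spec = builtin_scenarios()["divergence"]["S2"]
        rng = np.random.default_rng(0)
        for _ in range(2000):
            d = sample_prior(spec, rng)
            for k, (lo, hi) in spec.priors.items():
                assert lo <= d[k] <= hi
            assert d["t1"] > d["t2"]
        assert spec.priors["N_A"] == (10.0, 1.00e6)

    def test_degenerate_prior_is_constant(self):
        spec = ScenarioSpec(
            name="x", groups=["POP"], sample_sizes={"POP": 2},
            initial_sizes={"POP": "N"}, events=[],
            priors={"N": (100.0, 100.0)}, constraints=[],
        )
        rng = np.random.default_rng(0)
        assert all(sample_prior(spec, rng)["N"] == 100.0 for _ in range(10))

    def test_unsatisfiable_constraint_raises(self):
        spec = ScenarioSpec(
            name="x", groups=["POP"], sample_sizes={"POP": 2},
            initial_sizes={"POP": 100.0},
            events=[],
            priors={"a": (0.0, 1.0), "b": (5.0, 6.0)},
            constraints=[("a", "b")],
        )
        with pytest.raises(ValueError, match="unsatisfiable"):
            sample_prior(spec, np.random.default_rng(0))


class TestBuiltins:
    def test_s2_parameters_and_t1_prior(self):
        s2 = builtin_scenarios()["divergence"]["S2"]
        assert set(s2.priors) == {"N_A", "N_SW", "N_CE", "N_JP", "t1", "t2"}
        assert s2.priors["t1"] == (100.0, 5.00e7)

    def test_d3_has_seven_parameters(self):
        d3 = builtin_scenarios()["demography"]["D3"]
        assert set(d3.priors) == {"Na", "N2", "Nb", "N1", "t3", "tb", "t4"}

    def test_all_builtins_validate_and_simulate(self):
        rng = np.random.default_rng(6)
        scen = builtin_scenarios()
        for block in scen.values():
            for spec in block.values():
                draw = sample_prior(spec, rng)
                counts, sizes = simulate_group_counts(spec, draw, 5, rng)
                assert counts.shape == (len(spec.groups), 5)

    def test_scenario_json_round_trip(self):
        s5 = builtin_scenarios()["divergence"]["S5"]
        s5b = ScenarioSpec.from_json(s5.to_json())
        assert s5b.priors == s5.priors
        assert s5b.events == s5.events

    def test_unresolvable_scenario_rejected(self):
        with pytest.raises(ValueError, match="single ancestral"):
            ScenarioSpec(
                name="bad", groups=["A", "B"],
                sample_sizes={"A": 2, "B": 2},
                initial_sizes={"A": 100.0, "B": 100.0},
                events=[], priors={}, constraints=[],
            )


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        spec = builtin_scenarios()["divergence"]["S2"]
        draw = sample_prior(spec, np.random.default_rng(1))
        m1, _ = simulate_snps(spec, draw, 50, np.random.default_rng(2))
        m2, _ = simulate_snps(spec, draw, 50, np.random.default_rng(2))
        assert np.array_equal(m1.genotypes, m2.genotypes)

    def test_exchangeability_within_group(self):
        """Permuting individuals within a group leaves the group allele-count
        distribution unchanged (lineages are exchangeable)."""
        spec = builtin_scenarios()["divergence"]["S2"]
        draw = ParameterDraw("S2", {"N_A": 1e4, "N_SW": 1e4, "N_CE": 1e4,
                                    "N_JP": 1e4, "t1": 2e4, "t2": 1e4})
        rng = np.random.default_rng(8)
        m, pmap = simulate_snps(spec, draw, 400, rng)
        from relictgen.abc import summarize

        base = summarize(m, pmap).values
        perm = np.arange(m.n_individuals)
        sw = [i for i, s in enumerate(m.sample_ids) if s.startswith("SW")]
        perm[sw] = np.random.default_rng(0).permutation(sw)
        m2 = m.take_samples(perm)
        m2.sample_ids = m.sample_ids  # same labels, shuffled genotype rows
        assert np.allclose(summarize(m2, pmap).values, base)
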