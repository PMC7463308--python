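"""Coalescent simulation of biallelic SNP datasets under divergence and
demographic scenarios.

A :class:`ScenarioSpec` declares sampled groups with diploid sample sizes,
named parameters with uniform prior bounds (and ordering constraints such as
t1 > t2), and an ordered list of backward-in-time events: population merges,
instantaneous size changes, and admixture splits.  Sizes are diploid effective
sizes; times are in generations.

Each locus is an independent genealogy carrying exactly one mutation placed
uniformly on total branch length — the classic unlinked-SNP-per-locus model —
so every simulated locus is polymorphic in the pooled sample.  Diploid
genotypes are formed by random pairing of genes within populations
(Hardy-Weinberg); the kernel's gene lineages are exchangeable within a group,
so pairing consecutive genes is equivalent to a random pairing.

Built-in scenarios cover the five three-group divergence histories (S1-S5,
SW / CE / JP groups) and three single-lineage demographic histories
(D1 expansion, D2 expansion-shrinkage, D3 expansion-shrinkage-expansion),
with study-style uniform priors prefilled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .genotype_io import PopulationMap, SNPMatrix

__all__ = [
    "ScenarioSpec",
    "ParameterDraw",
    "sample_prior",
    "simulate_snps",
    "simulate_group_counts",
    "builtin_scenarios",
]

_EV_CODES = {"merge": _kernel.EV_MERGE, "resize": _kernel.EV_RESIZE,
             "admixture": _kernel.EV_ADMIX}


@dataclass
class ParameterDraw:
    """One sampled parameter vector for a scenario."""

    scenario: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class ScenarioSpec:
    """Demographic scenario: groups, priors, and backward-in-time events.

    ``initial_sizes`` maps each group to a parameter name (or number) giving
    its diploid size at sampling time.  Each event is a dict with keys
    ``time`` and ``type`` plus, per type:

    - ``merge``: ``source``, ``dest``, optional ``dest_size``
    - ``resize``: ``pop``, ``size``
    - ``admixture``: ``source``, ``dest_a``, ``dest_b``, ``prob``
      (lineage goes to ``dest_a`` with probability ``prob``)

    Field values that are strings refer to named parameters.
    """

    name: str
    groups: list[str]
    sample_sizes: dict[str, int]
    initial_sizes: dict[str, float | str]
    events: list[dict]
    priors: dict[str, tuple[float, float]]
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in self.sample_sizes or g not in self.initial_sizes:
                raise ValueError(f"group {g!r} missing sample size or initial size")
        for lo, hi in self.priors.values():
            if not lo <= hi:
                raise ValueError("prior lower bound exceeds upper bound")
        for big, small in self.constraints:
            if big not in self.priors or small not in self.priors:
                raise ValueError("constraint refers to unknown parameter")
        self._check_single_root()

    # -- validation -------------------------------------------------------
    def _midpoint_draw(self) -> ParameterDraw:
        vals = {k: 0.5 * (lo + hi) for k, (lo, hi) in self.priors.items()}
        # nudge constrained pairs into a valid ordering
        for big, small in self.constraints:
            if vals[big] <= vals[small]:
                vals[big], vals[small] = max(vals[big], vals[small]) * 1.01, min(
                    vals[big], vals[small]
                )
        return ParameterDraw(self.name, vals)

    def _check_single_root(self) -> None:
        draw = self._midpoint_draw()
        _, _, ev_type, ev_a, ev_b, ev_c, _ = self._assemble(draw)
        alive = set(range(len(self.groups)))
        for t, a, b, c in zip(ev_type, ev_a, ev_b, ev_c):
            if t == _kernel.EV_MERGE and a in alive:
                alive.discard(a)
                alive.add(b)
            elif t == _kernel.EV_ADMIX and a in alive:
                alive.discard(a)
                alive.update((b, c))
        if len(alive) != 1:
            raise ValueError(
                f"scenario {self.name!r} does not resolve to a single ancestral "
                f"population (remaining: {sorted(alive)})"
            )

    # -- assembly ---------------------------------------------------------
    def _resolve(self, v, draw: ParameterDraw) -> float:
        return float(draw.values[v]) if isinstance(v, str) else float(v)

    def _assemble(self, draw: ParameterDraw):
        """Kernel arrays (sizes0, ev_time, ev_type, ev_a, ev_b, ev_c, ev_param)."""
        gi = {g: i for i, g in enumerate(self.groups)}
        sizes0 = np.array(
            [self._resolve(self.initial_sizes[g], draw) for g in self.groups]
        )
        times, types, eas, ebs, ecs, params = [], [], [], [], [], []
        for ev in self.events:
            times.append(self._resolve(ev["time"], draw))
            typ = _EV_CODES[ev["type"]]
            types.append(typ)
            if ev["type"] == "merge":
                eas.append(gi[ev["source"]])
                ebs.append(gi[ev["dest"]])
                ecs.append(-1)
                params.append(
                    self._resolve(ev["dest_size"], draw) if "dest_size" in ev else -1.0
                )
            elif ev["type"] == "resize":
                eas.append(gi[ev["pop"]])
                ebs.append(-1)
                ecs.append(-1)
                params.append(self._resolve(ev["size"], draw))
            else:
                eas.append(gi[ev["source"]])
                ebs.append(gi[ev["dest_a"]])
                ecs.append(gi[ev["dest_b"]])
                params.append(self._resolve(ev["prob"], draw))
        order = np.argsort(np.asarray(times), kind="stable")
        arr = lambda x, dt: np.asarray(x, dtype=dt)[order]
        return (
            sizes0,
            arr(times, np.float64),
            arr(types, np.int64),
            arr(eas, np.int64),
            arr(ebs, np.int64),
            arr(ecs, np.int64),
            arr(params, np.float64),
        )

    def gene_groups(self) -> np.ndarray:
        """Initial population index of every sampled gene (2 per diploid)."""
        return np.repeat(
            np.arange(len(self.groups)),
            [2 * self.sample_sizes[g] for g in self.groups],
        ).astype(np.int64)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        d = json.loads(text)
        d["priors"] = {k: tuple(v) for k, v in d["priors"].items()}
        d["constraints"] = [tuple(c) for c in d["constraints"]]
        return cls(**d)


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def sample_prior(spec: ScenarioSpec, rng) -> ParameterDraw:
    """Uniform draw from the priors; ordering constraints resolved by redraw."""
    rng = _as_rng(rng)
    for _ in range(100_000):
        vals = {k: rng.uniform(lo, hi) for k, (lo, hi) in spec.priors.items()}
        if all(vals[big] > vals[small] for big, small in spec.constraints):
            return ParameterDraw(spec.name, vals)
    raise ValueError(f"constraints of {spec.name!r} unsatisfiable within bounds")


def _run_kernel(spec: ScenarioSpec, draw: ParameterDraw, n_loci: int, seed: int):
    sizes0, ev_t, ev_ty, ev_a, ev_b, ev_c, ev_p = spec._assemble(draw)
    if np.any(sizes0 <= 0):
        raise ValueError("population sizes must be positive")
    gene_pop = spec.gene_groups()
    derived = _kernel.simulate_scenario_loci(
        n_loci, gene_pop, len(spec.groups), sizes0, ev_t, ev_ty, ev_a, ev_b,
        ev_c, ev_p, seed,
    )
    if derived.size == 0 and n_loci > 0:
        raise ValueError(f"invalid draw for scenario {spec.name!r}: lineages stranded")
    return derived, gene_pop


def simulate_snps(
    spec: ScenarioSpec, draw: ParameterDraw, n_loci: int, rng
) -> tuple[SNPMatrix, PopulationMap]:
    """Simulate a complete diploid SNP matrix (one population per group)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = _as_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    derived, _ = _run_kernel(spec, draw, n_loci, seed)
    geno = (derived[:, 0::2] + derived[:, 1::2]).T.astype(np.int8)
    sample_ids, s2p = [], {}
    for g in spec.groups:
        for i in range(spec.sample_sizes[g]):
            sid = f"{g}_{i}"
            sample_ids.append(sid)
            s2p[sid] = g
    m = SNPMatrix(
        geno, sample_ids, [f"snp{j}" for j in range(n_loci)],
        [f"rad{j}" for j in range(n_loci)],
    )
    pmap = PopulationMap(s2p, {g: g for g in spec.groups},
                         {g: (0.0, 0.0) for g in spec.groups})
    return m, pmap


def simulate_group_counts(
    spec: ScenarioSpec, draw: ParameterDraw, n_loci: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: per-group derived allele counts (n_groups x n_loci) and
    per-group gene counts, skipping genotype-matrix construction."""
    rng = _as_rng(rng)
    seed = int(rng.integers(2**31 - 1))
    derived, gene_pop = _run_kernel(spec, draw, n_loci, seed)
    n_groups = len(spec.groups)
    onehot = np.zeros((len(gene_pop), n_groups))
    onehot[np.arange(len(gene_pop)), gene_pop] = 1.0
    counts = (derived.astype(np.float64) @ onehot).T
    sizes = onehot.sum(axis=0)
    return counts, sizes


# ---------------------------------------------------------------------------
# Built-in scenarios

#: Default diploid sample sizes of the three genomic groups (SW/CE/JP).
DEFAULT_SAMPLES = {"SW": 45, "CE": 75, "JP": 51}

_DIV_PRIORS = {
    "N_A": (10.0, 1.00e6),
    "N_SW": (10.0, 8.00e5),
    "N_CE": (10.0, 1.60e6),
    "N_JP": (10.0, 9.00e5),
    "t1": (100.0, 5.00e7),
    "t2": (100.0, 1.00e7),
}


def _divergence(name, events, priors, constraints):
    return ScenarioSpec(
        name=name,
        groups=["SW", "CE", "JP"],
        sample_sizes=dict(DEFAULT_SAMPLES),
        initial_sizes={"SW": "N_SW", "CE": "N_CE", "JP": "N_JP"},
        events=events,
        priors=priors,
        constraints=constraints,
    )


def _demographic(name, events, priors, constraints, n_samples=51):
    return ScenarioSpec(
        name=name,
        groups=["POP"],
        sample_sizes={"POP": n_samples},
        initial_sizes={"POP": "N1"},
        events=events,
        priors=priors,
        constraints=constraints,
    )


def builtin_scenarios() -> dict[str, dict[str, ScenarioSpec]]:
    """The five divergence scenarios (S1-S5) and three demographic scenarios
    (D1-D3) with study-style uniform priors prefilled (bounds editable)."""
    sub = lambda *keys: {k: _DIV_PRIORS[k] for k in keys}
    div = {
        # simultaneous three-way split at t1
        "S1": _divergence(
            "S1",
            [
                {"time": "t1", "type": "merge", "source": "CE", "dest": "SW"},
                {"time": "t1", "type": "merge", "source": "SW", "dest": "JP",
                 "dest_size": "N_A"},
            ],
            sub("N_A", "N_SW", "N_CE", "N_JP", "t1"),
            [],
        ),
        # JP splits first; CE arises from within SW at t2
        "S2": _divergence(
            "S2",
            [
                {"time": "t2", "type": "merge", "source": "CE", "dest": "SW"},
                {"time": "t1", "type": "merge", "source": "SW", "dest": "JP",
                 "dest_size": "N_A"},
            ],
            sub("N_A", "N_SW", "N_CE", "N_JP", "t1", "t2"),
            [("t1", "t2")],
        ),
        # CE splits first; JP arises from within SW at t2
        "S3": _divergence(
            "S3",
            [
                {"time": "t2", "type": "merge", "source": "JP", "dest": "SW"},
                {"time": "t1", "type": "merge", "source": "SW", "dest": "CE",
                 "dest_size": "N_A"},
            ],
            sub("N_A", "N_SW", "N_CE", "N_JP", "t1", "t2"),
            [("t1", "t2")],
        ),
        # SW splits first; JP arises from within CE at t2
        "S4": _divergence(
            "S4",
            [
                {"time": "t2", "type": "merge", "source": "JP", "dest": "CE"},
                {"time": "t1", "type": "merge", "source": "CE", "dest": "SW",
                 "dest_size": "N_A"},
            ],
            sub("N_A", "N_SW", "N_CE", "N_JP", "t1", "t2"),
            [("t1", "t2")],
        ),
        # SW and JP split at t1; CE founded by admixture between them at t2
        "S5": _divergence(
            "S5",
            [
                {"time": "t2", "type": "admixture", "source": "CE",
                 "dest_a": "SW", "dest_b": "JP", "prob": "ra"},
                {"time": "t1", "type": "merge", "source": "SW", "dest": "JP",
                 "dest_size": "N_A"},
            ],
            {**sub("N_A", "N_SW", "N_CE", "N_JP", "t1", "t2"),
             "ra": (0.001, 0.999)},
            [("t1", "t2")],
        ),
    }
    demo = {
        # single expansion: ancestral Na until t3, then current N1
        "D1": _demographic(
            "D1",
            [{"time": "t3", "type": "resize", "pop": "POP", "size": "Na"}],
            {"Na": (10.0, 1.00e5), "N1": (10.0, 1.20e6), "t3": (100.0, 1.00e7)},
            [],
        ),
        # expansion then shrinkage: Na -(t3)-> N2 -(tb)-> N1
        "D2": _demographic(
            "D2",
            [
                {"time": "tb", "type": "resize", "pop": "POP", "size": "N2"},
                {"time": "t3", "type": "resize", "pop": "POP", "size": "Na"},
            ],
            {"Na": (10.0, 1.00e5), "N2": (10.0, 2.00e6), "N1": (10.0, 1.20e6),
             "t3": (100.0, 1.60e7), "tb": (100.0, 1.00e7)},
            [("t3", "tb")],
        ),
        # expansion-shrinkage-expansion: Na -(t3)-> N2 -(tb)-> Nb -(t4)-> N1
        "D3": _demographic(
            "D3",
            [
                {"time": "t4", "type": "resize", "pop": "POP", "size": "Nb"},
                {"time": "tb", "type": "resize", "pop": "POP", "size": "N2"},
                {"time": "t3", "type": "resize", "pop": "POP", "size": "Na"},
            ],
            {"Na": (10.0, 1.00e5), "N2": (10.0, 2.00e6), "Nb": (10.0, 3.00e5),
             "N1": (10.0, 1.20e6), "t3": (100.0, 1.60e7), "tb": (100.0, 1.00e7),
             "t4": (100.0, 5.00e6)},
            [("t3", "tb"), ("tb", "t4")],
        ),
    }
    return {"divergence": div, "demography": demo}
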