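"""Study-like synthetic fixtures with known truth.

Generates the full input bundle every pipeline stage needs: a SNP matrix with
neutral loci from a coalescent scenario plus "adaptive" loci whose population
allele frequencies follow logistic clines in a chosen climate variable,
population metadata with coordinates, spatially autocorrelated climate fields
(current + shifted future), and a truth record naming the adaptive loci and
the generating parameters.

The default shape mirrors the study system: 35 populations in 3 groups
(24 Chinese populations split southwest/central-east plus 11 Japanese ones),
2-6 diploids each (171 individuals), a 1,383-locus complete matrix for
demographic inference and a several-thousand-locus matrix for selection
scans.  Adaptive loci are drawn independently of the coalescent (pure
frequency clines plus binomial sampling) — a deliberate simplification that
leaves no linkage structure between adaptive and neutral loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .coalescent_sim import ParameterDraw, ScenarioSpec, builtin_scenarios, _as_rng
from .env_association import SitePredictors
from .genotype_io import MISSING, PopulationMap, SNPMatrix
from .rasters import ClimateGrid

__all__ = ["StudyConfig", "make_climate_fields", "make_study", "make_future"]


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; defaults mirror the study system."""

    n_pops_per_group: dict[str, int] = field(
        default_factory=lambda: {"SW": 9, "CE": 15, "JP": 11}
    )
    individuals_range: tuple[int, int] = (2, 6)
    n_neutral: int = 1383
    n_adaptive: int = 20
    scenario: str = "S2"
    true_params: dict[str, float] = field(
        default_factory=lambda: {
            # study-style posterior medians (divergence model)
            "N_A": 6.92e5, "N_SW": 3.00e5, "N_CE": 9.13e5, "N_JP": 2.84e5,
            "t1": 6.39e6, "t2": 3.96e6,
        }
    )
    cline_variable: str = "BIO11"
    cline_slope: float = 5.0          # per SD of the climate variable
    cline_intercept: float = 0.0
    missingness: float = 0.05
    variables: tuple[str, ...] = ("BIO4", "BIO6", "BIO7", "BIO11", "BIO14", "BIO15")
    grid_shape: tuple[int, int] = (40, 60)
    extent: tuple[float, float, float, float] = (95.0, 145.0, 22.0, 42.0)
    smoothness: float = 4.0
    future_offsets: dict[str, float] = field(
        default_factory=lambda: {"BIO11": 1.5, "BIO6": 1.5, "BIO4": 0.5}
    )
    seed: int = 0


def make_climate_fields(
    extent: tuple[float, float, float, float],
    variables,
    smoothness: float,
    rng,
    shape: tuple[int, int] = (40, 60),
    site_coords: dict[str, tuple[float, float]] | None = None,
) -> tuple[ClimateGrid, SitePredictors | None]:
    """Spatially autocorrelated fields: smoothed Gaussian noise plus a
    latitudinal trend, one field per named variable.

    ``extent`` = (lon_min, lon_max, lat_min, lat_max); ``smoothness`` is the
    Gaussian smoothing radius in cells (larger -> flatter fields).  Site
    values are read from the containing cell.
    """
    rng = _as_rng(rng)
    ny, nx = shape
    lon_min, lon_max, lat_min, lat_max = extent
    x = np.linspace(lon_min, lon_max, nx)
    y = np.linspace(lat_max, lat_min, ny)        # north to south
    lat_field = np.broadcast_to(y[:, None], (ny, nx))
    fields = {}
    # noise amplitude decays with smoothness so the infinite-smoothness limit
    # is a flat (trend-only) field
    amp = 2.0 / (1.0 + (smoothness / 10.0) ** 2)
    for v in variables:
        noise = rng.normal(size=(ny, nx))
        if smoothness > 0:
            noise = gaussian_filter(noise, sigma=smoothness, mode="nearest")
            noise = noise / max(noise.std(), 1e-12)
        trend = (lat_field - lat_field.mean()) / max(lat_field.std(), 1e-12)
        fields[v] = amp * noise + trend
    grid = ClimateGrid(variables=fields, x=x, y=y, epoch="current")
    preds = None
    if site_coords is not None:
        preds = SitePredictors(grid.extract(site_coords))
    return grid, preds


def make_future(grid: ClimateGrid, offsets: dict[str, float],
                gradient: bool = False) -> ClimateGrid:
    """Shifted copy of ``grid`` (epoch "future"); geometry preserved.

    With ``gradient=True`` each offset ramps linearly from half to full
    magnitude south to north, giving a spatially varying shift.
    """
    new = {}
    ny = grid.shape[0]
    ramp = np.linspace(1.0, 0.5, ny)[:, None] if gradient else 1.0
    for v, arr in grid.variables.items():
        off = offsets.get(v, 0.0)
        new[v] = arr + off * ramp
    return grid.with_variables(new, epoch="future")


def _population_layout(config: StudyConfig, rng) -> PopulationMap:
    # groups occupy west-to-east longitude bands, like the study's SW/CE/JP
    lon_min, lon_max, lat_min, lat_max = config.extent
    bands = np.linspace(lon_min + 1, lon_max - 1, 4)
    s2p: dict[str, str] = {}
    p2g: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for gi, (group, n_pops) in enumerate(config.n_pops_per_group.items()):
        for k in range(n_pops):
            pop = f"{group}{k:02d}"
            p2g[pop] = group
            coords[pop] = (
                float(rng.uniform(lat_min + 1, lat_max - 1)),
                float(rng.uniform(bands[gi], bands[gi + 1])),
            )
            n_ind = int(rng.integers(config.individuals_range[0],
                                     config.individuals_range[1] + 1))
            for i in range(n_ind):
                s2p[f"{pop}_i{i}"] = pop
    return PopulationMap(s2p, p2g, coords)


def make_study(config: StudyConfig, rng=None) -> dict:
    """Generate the full synthetic study bundle.

    Returns a dict with keys ``snps``, ``popmap``, ``predictors``,
    ``grid_now``, ``grid_future``, and ``truth`` (adaptive locus ids, cline
    parameters, true demographic parameters, scenario name).
    """
    rng = _as_rng(config.seed if rng is None else rng)
    pmap = _population_layout(config, rng)
    grid_now, _ = make_climate_fields(
        config.extent, config.variables, config.smoothness, rng,
        shape=config.grid_shape, site_coords=None,
    )
    preds = SitePredictors(grid_now.extract(pmap.pop_coords))
    grid_future = make_future(grid_now, config.future_offsets, gradient=True)

    # neutral loci: coalescent under the configured scenario, resampled to the
    # per-population layout within groups
    scen = builtin_scenarios()
    spec = None
    for block in scen.values():
        if config.scenario in block:
            spec = block[config.scenario]
            break
    if spec is None:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    group_sizes = {
        g: sum(1 for s, p in pmap.sample_to_pop.items()
               if pmap.pop_to_group[p] == g)
        for g in pmap.groups
    }
    spec = ScenarioSpec(
        name=spec.name, groups=spec.groups,
        sample_sizes={g: group_sizes[g] for g in spec.groups},
        initial_sizes=spec.initial_sizes, events=spec.events,
        priors=spec.priors, constraints=spec.constraints,
    )
    missing_params = set(spec.priors) - set(config.true_params)
    if missing_params:
        raise ValueError(f"true_params missing {sorted(missing_params)}")
    draw = ParameterDraw(spec.name, dict(config.true_params))
    from .coalescent_sim import simulate_snps

    m_neutral, _ = simulate_snps(spec, draw, config.n_neutral, rng)
    # assign simulated individuals (grouped) to this study's samples in order
    sample_ids = []
    for g in spec.groups:
        for p in [p for p in pmap.populations if pmap.pop_to_group[p] == g]:
            sample_ids.extend(sorted(pmap.samples_of(p)))
    geno_neutral = m_neutral.genotypes

    # adaptive loci: logistic clines in the chosen variable + binomial noise
    xvar = preds.table[config.cline_variable]
    xz = (xvar - xvar.mean()) / max(xvar.std(), 1e-12)
    pop_of = [pmap.sample_to_pop[s] for s in sample_ids]
    adaptive_cols = []
    cline_params = []
    for a in range(config.n_adaptive):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pfreq = 1.0 / (1.0 + np.exp(-(config.cline_intercept
                                      + sign * config.cline_slope * xz)))
        col = np.array([rng.binomial(2, pfreq[p]) for p in pop_of], dtype=np.int8)
        adaptive_cols.append(col)
        cline_params.append({"variable": config.cline_variable,
                             "slope": float(sign * config.cline_slope),
                             "intercept": float(config.cline_intercept)})
    geno = np.column_stack([geno_neutral] + ([np.column_stack(adaptive_cols)]
                                             if adaptive_cols else []))
    n_total = geno.shape[1]
    locus_ids = [f"snp{j}" for j in range(config.n_neutral)] + [
        f"adaptive{j}" for j in range(config.n_adaptive)
    ]
    # missingness mask (never wiping out a whole locus)
    if config.missingness > 0:
        mask = rng.random(geno.shape) < config.missingness
        keep_one = rng.integers(0, geno.shape[0], size=n_total)
        mask[keep_one, np.arange(n_total)] = False
        geno = np.where(mask, MISSING, geno).astype(np.int8)
    snps = SNPMatrix(geno, sample_ids, locus_ids,
                     [f"rad{j}" for j in range(n_total)])
    truth = {
        "scenario": config.scenario,
        "true_params": dict(config.true_params),
        "adaptive_loci": [f"adaptive{j}" for j in range(config.n_adaptive)],
        "clines": cline_params,
        "config": asdict(config),
    }
    return {
        "snps": snps, "popmap": pmap, "predictors": preds,
        "grid_now": grid_now, "grid_future": grid_future, "truth": truth,
    }
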