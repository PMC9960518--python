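"""Synthetic cancer-registry generator.

Real registry case data are confidential, so every downstream stage of the
pipeline is exercised on synthetic registries that reproduce the statistical
structure the spatial Poisson model assumes: a tract geography with rook
adjacency, person-years stratified by 19 age groups x sex x race/ethnicity,
tract median income with controllable spatial autocorrelation, an intrinsic
CAR (ICAR) spatial risk field, and Poisson case counts

    O_cell ~ Poisson( person_years * exp(b0 + x'beta + f_tract) ).

The generating truth (betas, spatial field, tau^2) is kept alongside the
data so parameter-recovery tests can compare posterior estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geography import AdjacencyGraph, grid_adjacency
from .rates import AGE_GROUPS_19, QUARTILE_LABELS, StandardPopulation, assign_quartiles

RACE_LEVELS = ("NHW", "NHB", "Hispanic", "API")
SEX_LEVELS = ("male", "female")

#: Statewide-ish race/ethnicity mix used as the baseline tract composition.
BASE_RACE_MIX = {"NHW": 0.56, "NHB": 0.14, "Hispanic": 0.20, "API": 0.10}

#: Reference level per modelled factor; reference log-RRs are exactly 0.
REFERENCE_LEVELS = {
    "age_group": AGE_GROUPS_19[0],
    "sex": SEX_LEVELS[0],
    "race": RACE_LEVELS[0],
    "income_quartile": QUARTILE_LABELS[0],
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for a synthetic registry.

    Defaults give a desk-scale registry: a 15x15 tract grid, 5,000 residents
    per tract followed for 9 diagnosis years (10.125M person-years) and a
    reference-stratum rate of 2e-4 cases per person-year, i.e. on the order
    of 2,000 cases in total — large enough for stable estimation, small
    enough for MCMC in seconds. ``true_effects`` maps ``"factor:level"`` to
    a true log relative risk; the default truth carries the three signature
    effects studied downstream (female 0.6, NHB 1.5, top income quartile
    1.5, as rate ratios); unlisted non-reference levels default to log-RR 0.
    """

    grid_rows: int = 15
    grid_cols: int = 15
    n_years: int = 9
    tract_population: float = 5000.0
    age_groups: tuple[str, ...] = AGE_GROUPS_19
    race_levels: tuple[str, ...] = RACE_LEVELS
    sex_levels: tuple[str, ...] = SEX_LEVELS
    true_intercept: float = float(np.log(2e-4))
    true_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex:female": float(np.log(0.6)),
            "race:NHB": float(np.log(1.5)),
            "income_quartile:Q4": float(np.log(1.5)),
        }
    )
    spatial_variance: float = 0.01
    income_spatial_correlation: float = 0.5
    income_effect_via_field: float = 0.0
    segregation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_tracts < 4:
            raise ValueError("need at least 4 tracts (a 2x2 grid)")
        if len(self.age_groups) != 19:
            raise ValueError("exactly 19 age groups are required")
        if self.spatial_variance < 0:
            raise ValueError("spatial_variance must be nonnegative")
        if not -1.0 <= self.income_spatial_correlation <= 1.0:
            raise ValueError("income_spatial_correlation must lie in [-1, 1]")
        if not 0.0 <= self.segregation <= 1.0:
            raise ValueError("segregation must lie in [0, 1]")

    @property
    def n_tracts(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters: the recovery target for the spatial model."""

    intercept: float
    betas: dict[str, float]
    spatial_field: np.ndarray
    tau2: float

    def __post_init__(self):
        f = np.asarray(self.spatial_field, dtype=float)
        if abs(f.sum()) > 1e-9:
            raise ValueError("spatial field must sum to zero")
        object.__setattr__(self, "spatial_field", f)

    def to_jsonable(self) -> dict:
        return {
            "intercept": self.intercept,
            "betas": dict(self.betas),
            "spatial_field": self.spatial_field.tolist(),
            "tau2": self.tau2,
        }


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_icar_field(
    graph: AdjacencyGraph, variance: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one intrinsic-CAR field over the graph, centered to sum zero.

    The ICAR density is pi(f) ~ exp(-(1/2 tau^2) sum_{i~j} (f_i - f_j)^2),
    a degenerate Gaussian with precision L / tau^2 (L the graph Laplacian).
    Sampling goes through the eigendecomposition of L: independent normal
    coefficients with variance tau^2 / lambda_k on each non-null eigenvector.
    The null space (the constant vector, for a connected graph) carries no
    mass; the draw is re-centered to machine-exact sum zero.
    """
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    comps = graph.components()
    if len(comps) > 1:
        raise ValueError(
            f"graph has {len(comps)} connected components; ICAR requires a "
            f"connected graph (components: {[sorted(map(str, c))[:3] for c in comps]})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, vec = np.linalg.eigh(graph.laplacian())
    # connected graph: exactly one (numerically) zero eigenvalue
    nonnull = lam > 1e-10 * lam[-1]
    coef = rng.standard_normal(int(nonnull.sum())) * np.sqrt(variance / lam[nonnull])
    f = vec[:, nonnull] @ coef
    f -= f.mean()
    return f


def make_geography(config: SyntheticConfig) -> tuple[pd.DataFrame, AdjacencyGraph]:
    """Generate the tract table (geometry, income, poverty) and rook graph.

    Tracts are unit squares on a grid. Median income is log-normal around
    $70k with a spatially smoothed component mixed in at weight
    ``income_spatial_correlation``, so income quartiles form spatial
    clusters the way real census-tract income does; the tract-value income
    quartile is attached as ``income_quartile``. Poverty is a decreasing
    logistic function of log income plus noise.
    """
    graph = grid_adjacency(config.grid_rows, config.grid_cols)
    rng_smooth, rng_noise, rng_pov = _child_rngs(config.seed ^ 0x5EED, 3)

    n = config.n_tracts
    rho = config.income_spatial_correlation
    if rho != 0.0:
        smooth = sample_icar_field(graph, 1.0, rng_smooth)
        smooth = smooth / smooth.std()
    else:
        smooth = np.zeros(n)
    noise = rng_noise.standard_normal(n)
    z = np.sign(rho) * abs(rho) * smooth + np.sqrt(1 - rho**2) * noise
    log_income = np.log(70_000) + 0.35 * z
    income = np.exp(log_income)
    poverty = 100.0 / (1.0 + np.exp((log_income - np.log(55_000)) / 0.35
                                    + 0.3 * rng_pov.standard_normal(n)))

    rows, cols = np.divmod(np.arange(n), config.grid_cols)
    tracts = pd.DataFrame(
        {
            "tract_id": list(graph.node_ids),
            "row": rows,
            "col": cols,
            "median_income": income,
            "poverty_pct": poverty,
            "geometry": [box(c, -float(r) - 1.0, c + 1.0, -float(r)) for r, c in zip(rows, cols)],
        }
    )
    tracts["income_quartile"] = assign_quartiles(
        tracts.set_index("tract_id")["median_income"], method="tract"
    ).to_numpy()
    return tracts, graph


def make_population(config: SyntheticConfig, tracts: pd.DataFrame) -> pd.DataFrame:
    """Person-years per (tract, age group, sex, race/ethnicity) cell.

    Each tract holds ``tract_population`` residents observed for ``n_years``
    years. The age pyramid follows the 2000 US standard distribution, sexes
    split evenly, and the race mix tilts with the tract's income rank when
    ``segregation`` > 0 (NHW share rising with income, NHB/Hispanic falling,
    as in segregated metropolitan areas) so race x income joint effects are
    estimable. Proportions sum to one exactly, so total person-years equal
    n_tracts * tract_population * n_years up to float rounding.
    """
    age_p = StandardPopulation.us2000_19ages().weights
    n = len(tracts)
    income_rank = tracts["median_income"].rank(method="average").to_numpy() / n - 0.5

    base = np.array([BASE_RACE_MIX[r] for r in config.race_levels])
    tilt = np.array(
        [{"NHW": 1.0, "NHB": -1.0, "Hispanic": -0.7, "API": 0.7}.get(r, 0.0)
         for r in config.race_levels]
    )
    # income-rank-dependent logit tilt; softmax keeps each tract's mix on the simplex
    logits = np.log(base)[None, :] + 2.0 * config.segregation * income_rank[:, None] * tilt[None, :]
    race_p = np.exp(logits)
    race_p /= race_p.sum(axis=1, keepdims=True)

    py_tract = config.tract_population * config.n_years
    cells = []
    for t_pos, tract in enumerate(tracts["tract_id"]):
        for a_pos, age in enumerate(config.age_groups):
            for sex in config.sex_levels:
                for r_pos, race in enumerate(config.race_levels):
                    cells.append(
                        (
                            tract,
                            age,
                            sex,
                            race,
                            py_tract * age_p[a_pos] * 0.5 * race_p[t_pos, r_pos],
                        )
                    )
    return pd.DataFrame(
        cells, columns=["tract_id", "age_group", "sex", "race", "person_years"]
    )


def make_truth(config: SyntheticConfig, graph: AdjacencyGraph) -> SyntheticTruth:
    """Assemble the full generating truth for a configuration.

    All non-reference levels of the four modelled factors get an explicit
    log-RR (0 unless overridden in ``config.true_effects``); the spatial
    field is one ICAR draw at ``spatial_variance`` (all zeros when the
    variance is 0).
    """
    betas: dict[str, float] = {}
    level_sets = {
        "age_group": config.age_groups,
        "sex": config.sex_levels,
        "race": config.race_levels,
        "income_quartile": QUARTILE_LABELS,
    }
    for factor, levels in level_sets.items():
        for level in levels:
            if level == REFERENCE_LEVELS[factor]:
                continue
            betas[f"{factor}:{level}"] = float(
                config.true_effects.get(f"{factor}:{level}", 0.0)
            )
    unknown = set(config.true_effects) - set(betas)
    if unknown:
        raise ValueError(f"true_effects for unknown or reference level(s): {sorted(unknown)}")
    if config.spatial_variance > 0:
        f = sample_icar_field(graph, config.spatial_variance, config.seed ^ 0xF1E1D)
    else:
        f = np.zeros(graph.n_nodes)
    return SyntheticTruth(
        intercept=config.true_intercept,
        betas=betas,
        spatial_field=f,
        tau2=config.spatial_variance,
    )


def simulate_cases(
    population: pd.DataFrame,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    tracts: pd.DataFrame,
    graph: AdjacencyGraph,
) -> pd.DataFrame:
    """Draw Poisson case counts for every population cell.

    Cell mean = person_years * exp(intercept + sum of the cell's non-reference
    log-RRs + tract spatial effect). Raises if a non-reference level present
    in the population has no beta in the truth.
    """
    pop = population.merge(
        tracts[["tract_id", "income_quartile"]], on="tract_id", how="left"
    )
    eta = np.full(len(pop), truth.intercept)
    for factor in ("age_group", "sex", "race", "income_quartile"):
        ref = REFERENCE_LEVELS[factor]
        levels = pop[factor].astype(str)
        missing = sorted(
            {
                f"{factor}:{lv}"
                for lv in levels.unique()
                if lv != ref and f"{factor}:{lv}" not in truth.betas
            }
        )
        if missing:
            raise ValueError(f"truth.betas missing level(s): {missing}")
        eta += levels.map(
            lambda lv, _f=factor: truth.betas.get(f"{_f}:{lv}", 0.0)
        ).to_numpy()
    tract_index = pop["tract_id"].map(graph.index_of).to_numpy()
    eta += truth.spatial_field[tract_index]

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xCA5E5)))
    mean = pop["person_years"].to_numpy() * np.exp(eta)
    out = population.copy()
    out["cases"] = rng.poisson(mean)
    return out[["tract_id", "age_group", "sex", "race", "cases", "person_years"]]


def simulate_registry(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, AdjacencyGraph, pd.DataFrame, SyntheticTruth]:
    """One-call generator: (tract table, adjacency, stratified counts, truth)."""
    tracts, graph = make_geography(config)
    population = make_population(config, tracts)
    truth = make_truth(config, graph)
    counts = simulate_cases(population, truth, config, tracts, graph)
    return tracts, graph, counts, truth
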