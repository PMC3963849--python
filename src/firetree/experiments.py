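"""Experiment designs: single-site runs, sensitivity grids, spatial ensembles.

Four designs mirror the model's analysis programme:

* a single-site run pairing a long stochastic trajectory with the discretized
  chain's stationary cover distribution;
* two sensitivity sweeps of the bimodality index over triangular parameter
  domains — demographic (no-fire vs fire retention, constrained to
  alpha_f <= alpha_nf) and fire-regime (target fire probabilities at the two
  steady states, constrained to p_at_f > p_at_nf and inverted to thresholds);
* a spatial ensemble of independently parametrised sites sampled at one
  instant, mimicking how remote-sensing cover distributions are collected
  (space traded for time);
* a three-size-class run whose fire feedback is driven by the canopy classes
  only.

All randomness descends from a single master seed through counter-based child
seeds (SeedSequence spawn keys), so every grid point and site is reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import statistics as stats
from .configs import scalar_config
from .markov_chain import DiscretizedChain, cover_distribution, discretize
from .model_core import (
    ConfigurationError,
    ModelConfig,
    SimulationResult,
    invert_fire_thresholds,
    simulate,
    stability_check,
)
from .statistics import (
    BimodalityReport,
    CoverHistogram,
    FireChainEstimate,
    PermanenceSummary,
    bimodality_index,
    estimate_fire_chain,
    histogram_by_dynamic,
    permanence_ratios,
    pooled_bimodality,
)

__all__ = [
    "SingleSiteResult",
    "SensitivityGrid",
    "EnsembleDesign",
    "EnsembleResult",
    "ThreeClassResult",
    "child_rng",
    "run_single_site",
    "sensitivity_demographic",
    "sensitivity_fire",
    "run_ensemble",
    "run_three_class",
    "bimodal_site_design",
    "two_band_site_design",
]


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-based child generator: reproducible and order-independent."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# single site


@dataclass(frozen=True)
class SingleSiteResult:
    result: SimulationResult
    permanence: PermanenceSummary
    fire_chain: FireChainEstimate
    hist_total: CoverHistogram
    hist_fire: CoverHistogram
    hist_nofire: CoverHistogram
    chain: DiscretizedChain
    stationary_cover: CoverHistogram
    bimodality_trajectory: BimodalityReport
    bimodality_chain: BimodalityReport


def run_single_site(
    config: ModelConfig,
    x0=None,
    horizon: int = 5000,
    delta: float = 0.01,
    bin_width: float = 0.1,
    burn_in: int = stats.DEFAULT_BURN_IN,
) -> SingleSiteResult:
    """Full single-site analysis: trajectory statistics plus the chain view.

    The chain (and its stationary cover distribution) is seed-independent;
    the trajectory uses the config seed.
    """
    if x0 is None:
        x0 = np.zeros(config.n)
    result = simulate(config, x0, horizon)
    perm = permanence_ratios(result.fires, burn_in)
    h_tot, h_f, h_nf = histogram_by_dynamic(result, bin_width, burn_in)
    chain = discretize(config, delta)
    return SingleSiteResult(
        result=result,
        permanence=perm,
        fire_chain=estimate_fire_chain(result.fires),
        hist_total=h_tot,
        hist_fire=h_f,
        hist_nofire=h_nf,
        chain=chain,
        stationary_cover=cover_distribution(chain, bin_width),
        bimodality_trajectory=bimodality_index(result, bin_width, burn_in),
        bimodality_chain=bimodality_index(chain, bin_width),
    )


# ---------------------------------------------------------------------------
# sensitivity grids


@dataclass(frozen=True, eq=False)
class SensitivityGrid:
    """Bimodality index and mean cover over a triangular parameter domain.

    ``B[i, j]`` and ``mean_cover[i, j]`` correspond to
    (axis2_values[i], axis1_values[j]); infeasible points are NaN.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    B: np.ndarray
    mean_cover: np.ndarray
    master_seed: int

    @property
    def feasible(self) -> np.ndarray:
        return ~np.isnan(self.B)

    @property
    def bimodal_fraction(self) -> float:
        """Fraction of feasible points classified bimodal (B >= 0.1)."""
        feas = self.feasible
        if not feas.any():
            return float("nan")
        return float((self.B[feas] >= stats.B_THRESHOLD).mean())


def _grid_point_stats(
    config: ModelConfig,
    master_seed: int,
    key: tuple[int, int],
    horizon: int,
    burn_in: int,
    bin_width: float,
) -> tuple[float, float]:
    rng = child_rng(master_seed, *key)
    result = simulate(config, np.zeros(config.n), horizon, rng=rng)
    report = bimodality_index(result, bin_width, burn_in)
    return report.B, float(result.effective_cover[burn_in : result.horizon].mean())


def sensitivity_demographic(
    base_config: ModelConfig,
    grid_step: float = 0.05,
    horizon: int = 5000,
    burn_in: int = stats.DEFAULT_BURN_IN,
    bin_width: float = 0.1,
    master_seed: int | None = None,
) -> SensitivityGrid:
    """Sweep the two scalar retention parameters over their triangular domain.

    Axis 1 is the fire retention alpha_f (resistance of trees to fire), axis 2
    the no-fire retention alpha_nf (how fast cover grows without fire);
    feasibility requires alpha_f <= alpha_nf and a contracting update map.
    Recruitment and fire parameters are held at the base configuration.
    """
    if base_config.n != 1:
        raise ConfigurationError("demographic sensitivity sweep is scalar-only")
    if master_seed is None:
        master_seed = base_config.seed
    n_vals = round(1.0 / grid_step)
    values = np.linspace(grid_step, 1.0, n_vals)
    a = base_config.recruitment.a
    f = base_config.fire
    B = np.full((n_vals, n_vals), np.nan)
    mean = np.full((n_vals, n_vals), np.nan)
    for i, alpha_nf in enumerate(values):
        for j, alpha_f in enumerate(values):
            if alpha_f > alpha_nf:
                continue
            config = scalar_config(
                alpha_nf, alpha_f, a, f.theta1, f.theta2, f.p_max, f.p_min
            )
            if not all(
                [stability_check(config).stable_nf, stability_check(config).stable_f]
            ):
                continue
            B[i, j], mean[i, j] = _grid_point_stats(
                config, master_seed, (i, j), horizon, burn_in, bin_width
            )
    if np.all(np.isnan(B)):
        raise ConfigurationError("no feasible points in the demographic grid")
    return SensitivityGrid(
        axis1_name="alpha_f",
        axis1_values=values,
        axis2_name="alpha_nf",
        axis2_values=values,
        B=B,
        mean_cover=mean,
        master_seed=master_seed,
    )


def sensitivity_fire(
    base_config: ModelConfig,
    grid_step: float = 0.05,
    horizon: int = 5000,
    burn_in: int = stats.DEFAULT_BURN_IN,
    bin_width: float = 0.1,
    master_seed: int | None = None,
) -> SensitivityGrid:
    """Sweep the target fire probabilities at the two steady states.

    Axis 1 is p at the disturbed steady state, axis 2 p at the undisturbed
    one; the domain is triangular (p_at_f > p_at_nf, diagonal excluded) and
    each point is realised by inverting the fire thresholds.  Points whose
    thresholds escape [0, 1] are infeasible and left absent.
    """
    if base_config.n != 1:
        raise ConfigurationError("fire sensitivity sweep is scalar-only")
    if master_seed is None:
        master_seed = base_config.seed
    n_vals = round(1.0 / grid_step) - 1
    values = np.linspace(grid_step, 1.0 - grid_step, n_vals)
    a = base_config.recruitment.a
    alpha_nf = float(base_config.stages.A_nf[0, 0])
    alpha_f = float(base_config.stages.A_f[0, 0])
    B = np.full((n_vals, n_vals), np.nan)
    mean = np.full((n_vals, n_vals), np.nan)
    for i, p_nf in enumerate(values):
        for j, p_f in enumerate(values):
            if p_f <= p_nf:
                continue
            try:
                th1, th2 = invert_fire_thresholds(p_nf, p_f, base_config)
            except ConfigurationError:
                continue
            config = scalar_config(alpha_nf, alpha_f, a, th1, th2)
            B[i, j], mean[i, j] = _grid_point_stats(
                config, master_seed, (i, j), horizon, burn_in, bin_width
            )
    if np.all(np.isnan(B)):
        raise ConfigurationError("no feasible points in the fire grid")
    return SensitivityGrid(
        axis1_name="p_at_f",
        axis1_values=values,
        axis2_name="p_at_nf",
        axis2_values=values,
        B=B,
        mean_cover=mean,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# spatial ensemble


#: a parameter range: one interval, or a union of two disjoint intervals
Range = tuple[float, float] | tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class EnsembleDesign:
    """Design of a spatial-sampling ensemble of independent scalar sites.

    ``parameter_ranges`` maps parameter names (alpha_nf, alpha_f, a, theta1,
    theta2) to uniform sampling intervals; a pair of intervals splits the
    sites evenly (even/odd site index) between the two bands.  Parameters not
    listed are taken from the base configuration.
    """

    n_sites: int = 1000
    horizon: int = 5000
    sample_time: int = 300
    burn_in: int = stats.DEFAULT_BURN_IN
    stride: int = 100
    master_seed: int = 0
    parameter_ranges: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_time <= self.burn_in:
            raise ConfigurationError(
                f"sample_time {self.sample_time} must exceed burn-in {self.burn_in}"
            )
        if self.sample_time > self.horizon:
            raise ConfigurationError("sample_time must lie within the horizon")


def bimodal_site_design(master_seed: int = 0, **overrides) -> EnsembleDesign:
    """Ensemble whose sites individually sit in the bimodal regime.

    Narrow band for the no-fire retention (tree mortality without fire varies
    little between species), wider bands for the fire retention and
    recruitment (species differ strongly in fire vulnerability), thresholds
    drawn so that both steady states keep a low risk of being left.  The
    bands bracket the fast-growth bimodal example configuration
    (:func:`~firetree.configs.scalar_bimodal_config`); they are
    package-chosen stand-ins, see docs/methods.md.
    """
    ranges = {
        "alpha_nf": (0.88, 0.92),
        "alpha_f": (0.03, 0.10),
        "a": (0.40, 0.50),
        "theta1": (0.38, 0.45),
        "theta2": (0.88, 0.95),
    }
    return EnsembleDesign(
        master_seed=master_seed, parameter_ranges=ranges, **overrides
    )


def two_band_site_design(master_seed: int = 0, **overrides) -> EnsembleDesign:
    """Ensemble mixing a high-cover and a low-cover unimodal regime.

    The fire retention is drawn from a union of two disjoint bands: very
    fire-vulnerable trees (sites collapse to a low-cover, frequently burned
    state) and very fire-resistant trees (sites settle at high cover where
    fire is rare).  Each site alone is unimodal; the pooled spatial sample is
    bimodal.
    """
    ranges = {
        "alpha_nf": (0.96, 0.99),
        "alpha_f": ((0.05, 0.2), (0.85, 0.95)),
        "a": (0.08, 0.15),
    }
    return EnsembleDesign(
        master_seed=master_seed, parameter_ranges=ranges, **overrides
    )


@dataclass(frozen=True, eq=False)
class EnsembleResult:
    design: EnsembleDesign
    covers_at_sample: np.ndarray
    fires_at_sample: np.ndarray
    pooled_histogram: CoverHistogram
    pooled_bimodality: BimodalityReport
    B_times: np.ndarray
    B_series: np.ndarray


def _draw_site_params(
    design: EnsembleDesign, base_config: ModelConfig, site: int, rng
) -> dict:
    f = base_config.fire
    params = {
        "alpha_nf": float(base_config.stages.A_nf[0, 0]),
        "alpha_f": float(base_config.stages.A_f[0, 0]),
        "a": base_config.recruitment.a,
        "theta1": f.theta1,
        "theta2": f.theta2,
    }
    for name, rng_spec in design.parameter_ranges.items():
        if name not in params:
            raise ConfigurationError(f"unknown ensemble parameter {name!r}")
        if isinstance(rng_spec[0], (tuple, list)):
            lo, hi = rng_spec[site % 2]  # even split between the two bands
        else:
            lo, hi = rng_spec
        params[name] = float(rng.uniform(lo, hi))
    return params


def run_ensemble(
    design: EnsembleDesign,
    base_config: ModelConfig,
    bin_width: float = 0.1,
) -> EnsembleResult:
    """Simulate independent sites and pool (cover, fire status) at one instant.

    Each site draws its parameters and its fire history from a child
    generator keyed by the site index, then the pooled sample at
    ``design.sample_time`` is summarised exactly like a field campaign
    snapshot; the bimodality index is also tracked at every ``stride`` years.
    """
    if base_config.n != 1:
        raise ConfigurationError("spatial ensembles are scalar-only")
    times = np.arange(design.burn_in, design.horizon + 1, design.stride)
    covers_t = np.empty((design.n_sites, times.size))
    fires_t = np.empty((design.n_sites, times.size), dtype=np.int8)
    covers_s = np.empty(design.n_sites)
    fires_s = np.empty(design.n_sites, dtype=np.int8)
    for site in range(design.n_sites):
        rng = child_rng(design.master_seed, site)
        p = _draw_site_params(design, base_config, site, rng)
        config = scalar_config(
            p["alpha_nf"], p["alpha_f"], p["a"], p["theta1"], p["theta2"],
            p_max=base_config.fire.p_max, p_min=base_config.fire.p_min,
        )
        result = simulate(config, [0.0], design.horizon, rng=rng)
        total = result.total_cover
        # fire label of the final state defaults to the last drawn indicator
        fire_at = np.append(result.fires, result.fires[-1])
        covers_t[site] = total[times]
        fires_t[site] = fire_at[times]
        covers_s[site] = total[design.sample_time]
        fires_s[site] = fire_at[design.sample_time]
    pooled = pooled_bimodality(covers_s, fires_s, bin_width)
    B_series = np.array(
        [
            pooled_bimodality(covers_t[:, k], fires_t[:, k], bin_width).B
            for k in range(times.size)
        ]
    )
    return EnsembleResult(
        design=design,
        covers_at_sample=covers_s,
        fires_at_sample=fires_s,
        pooled_histogram=CoverHistogram.from_values(covers_s, bin_width),
        pooled_bimodality=pooled,
        B_times=times,
        B_series=B_series,
    )


# ---------------------------------------------------------------------------
# three size classes


@dataclass(frozen=True)
class ThreeClassResult:
    result: SimulationResult
    permanence: PermanenceSummary
    fire_chain: FireChainEstimate
    cover_histogram: CoverHistogram
    bimodality: BimodalityReport
    stationary_cover: CoverHistogram | None
    chain: DiscretizedChain | None


def run_three_class(
    config: ModelConfig,
    x0=None,
    horizon: int = 5000,
    bin_width: float = 0.1,
    burn_in: int = stats.DEFAULT_BURN_IN,
    delta: float | None = None,
    samples_per_axis: int = 5,
) -> ThreeClassResult:
    """Run the three-size-class example (fire driven by the canopy classes).

    ``delta`` optionally adds the discretized-chain view of the stationary
    cover distribution (sampled Ulam transitions; cost grows as (1/delta)^3).
    """
    if config.n != 3:
        raise ConfigurationError(f"three-class experiment needs n=3, got n={config.n}")
    if x0 is None:
        x0 = np.zeros(3)
    result = simulate(config, x0, horizon)
    covers = result.effective_cover[burn_in:horizon]
    chain = stationary = None
    if delta is not None:
        chain = discretize(config, delta, samples_per_axis)
        stationary = cover_distribution(chain, bin_width)
    return ThreeClassResult(
        result=result,
        permanence=permanence_ratios(result.fires, burn_in),
        fire_chain=estimate_fire_chain(result.fires),
        cover_histogram=CoverHistogram.from_values(covers, bin_width),
        bimodality=bimodality_index(result, bin_width, burn_in),
        stationary_cover=stationary,
        chain=chain,
    )
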