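"""Switched Lefkovitch model of tree-cover dynamics under a fire feedback.

The state is a vector ``x(t)`` of per-size-class tree-cover fractions on the
unit simplex (every component in [0, 1], total cover at most 1).  Each year one
of two nonnegative stage-transition (Lefkovitch) matrices is applied — ``A_f``
if a fire occurred, ``A_nf`` otherwise — followed by recruitment of new
seedlings into the smallest class:

    x(t+1) = A(F(t)) x(t) + a * (1 - 1' A(F(t)) x(t)) * e1

where ``F(t)`` is a Bernoulli fire indicator drawn with probability
``p(C(t))``, a non-increasing piecewise-linear function of the effective tree
cover ``C`` (more trees -> less grass fuel -> less fire).  The result is a
Markov jump linear system: two individually stable affine dynamics, each with
one fixed point, switched by a state-dependent fire process.  Bimodal cover
distributions can emerge from the switching alone, without bistability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "SimplexError",
    "UnstableDynamicsError",
    "FireProbabilityModel",
    "StagePair",
    "Recruitment",
    "ModelConfig",
    "SteadyStates",
    "StabilityReport",
    "SimulationResult",
    "validate_state",
    "fire_probability",
    "effective_cover",
    "effective_update_matrix",
    "step",
    "simulate",
    "steady_state",
    "steady_states",
    "stability_check",
    "invert_fire_thresholds",
]

#: numerical tolerance for simplex membership checks
SIMPLEX_TOL = 1e-12
#: violations up to this size are treated as float noise and clipped
CLIP_TOL = 1e-9


class ConfigurationError(ValueError):
    """An invalid model configuration (violated type invariant)."""


class SimplexError(RuntimeError):
    """A state left the unit simplex by more than the clipping tolerance."""


class UnstableDynamicsError(RuntimeError):
    """The selected dynamic has no attracting fixed point."""


def validate_state(x, n: int | None = None, *, tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Validate and return a tree-cover state vector.

    Checks that every component lies in [0, 1] and the total cover is at most
    1, both up to `tol`; tiny violations are clipped.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float)).ravel()
    if n is not None and arr.size != n:
        raise ConfigurationError(f"state has {arr.size} classes, expected {n}")
    if arr.size < 1:
        raise ConfigurationError("state must have at least one size class")
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise SimplexError(f"state components outside [0, 1]: {arr!r}")
    total = arr.sum()
    if total > 1 + tol:
        raise SimplexError(f"total cover {total} exceeds 1")
    return np.clip(arr, 0.0, 1.0)


@dataclass(frozen=True)
class FireProbabilityModel:
    """Piecewise-linear decreasing fire probability p(C).

    ``p = p_max`` for effective cover C <= theta1, ``p = p_min`` for
    C >= theta2, and linear in between.  theta1 anchors the fuel load below
    which fire is (near) certain, theta2 the load above which it is (near)
    impossible.  ``cover_mask`` lists the 1-based size classes whose covers sum
    to the effective cover driving the feedback (``None`` = all classes).
    """

    theta1: float
    theta2: float
    p_max: float = 1.0
    p_min: float = 0.0
    cover_mask: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta1 <= self.theta2 <= 1.0):
            raise ConfigurationError(
                f"need 0 <= theta1 <= theta2 <= 1, got ({self.theta1}, {self.theta2})"
            )
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ConfigurationError(
                f"need 0 <= p_min <= p_max <= 1, got ({self.p_min}, {self.p_max})"
            )
        if self.cover_mask is not None:
            mask = tuple(sorted(int(i) for i in self.cover_mask))
            if len(mask) == 0:
                raise ConfigurationError("cover_mask must be nonempty")
            if len(set(mask)) != len(mask):
                raise ConfigurationError("cover_mask indices must be unique")
            if mask[0] < 1:
                raise ConfigurationError("cover_mask uses 1-based class indices")
            object.__setattr__(self, "cover_mask", mask)


@dataclass(frozen=True)
class StagePair:
    """The two Lefkovitch stage-transition matrices (no-fire and fire).

    Entry (i, j) is the proportion of cover of class j moving into class i in
    one year; column sums at most 1 (the deficit is mortality).
    """

    A_nf: np.ndarray
    A_f: np.ndarray

    def __post_init__(self) -> None:
        a_nf = np.atleast_2d(np.asarray(self.A_nf, dtype=float))
        a_f = np.atleast_2d(np.asarray(self.A_f, dtype=float))
        for name, a in (("A_nf", a_nf), ("A_f", a_f)):
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ConfigurationError(f"{name} must be square, got shape {a.shape}")
            if np.any(a < 0):
                raise ConfigurationError(f"{name} has negative entries")
            colsums = a.sum(axis=0)
            bad = np.nonzero(colsums > 1 + SIMPLEX_TOL)[0]
            if bad.size:
                raise ConfigurationError(
                    f"{name} column {bad[0] + 1} sums to {colsums[bad[0]]:.6g} > 1"
                )
        if a_nf.shape != a_f.shape:
            raise ConfigurationError("A_nf and A_f must have the same dimension")
        object.__setattr__(self, "A_nf", a_nf)
        object.__setattr__(self, "A_f", a_f)
        self.A_nf.setflags(write=False)
        self.A_f.setflags(write=False)

    @property
    def n(self) -> int:
        return self.A_nf.shape[0]


@dataclass(frozen=True)
class Recruitment:
    """Recruitment of new seedlings into the smallest size class.

    With ``space_limited`` (default) the recruited cover is ``a`` times the
    free space left after the survival/transition update, keeping the state on
    the simplex for any valid stage matrices.  With ``space_limited=False`` a
    constant cover ``a`` is recruited each year (the state can then leave the
    simplex for aggressive configurations, which raises an error).
    """

    a: float
    space_limited: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ConfigurationError(f"recruitment rate must be in [0, 1], got {self.a}")


@dataclass(frozen=True)
class ModelConfig:
    """Bundle of stage matrices, recruitment, fire feedback and RNG seed."""

    stages: StagePair
    recruitment: Recruitment
    fire: FireProbabilityModel
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.stages.n
        mask = self.fire.cover_mask
        if mask is not None and mask[-1] > n:
            raise ConfigurationError(
                f"cover_mask index {mask[-1]} out of range for n={n} classes"
            )

    @property
    def n(self) -> int:
        return self.stages.n

    def matrix(self, fired: bool) -> np.ndarray:
        return self.stages.A_f if fired else self.stages.A_nf

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=int(seed))


def fire_probability(C, fire: FireProbabilityModel):
    """Fire probability at effective cover ``C`` (scalar or array).

    Non-increasing piecewise-linear interpolation between (theta1, p_max) and
    (theta2, p_min); a step function when theta1 == theta2.
    """
    c = np.asarray(C, dtype=float)
    if np.any(c < -SIMPLEX_TOL) or np.any(c > 1 + SIMPLEX_TOL):
        raise ConfigurationError(f"effective cover must be in [0, 1], got {C}")
    if fire.theta2 == fire.theta1:
        p = np.where(c <= fire.theta1, fire.p_max, fire.p_min)
    else:
        frac = np.clip((c - fire.theta1) / (fire.theta2 - fire.theta1), 0.0, 1.0)
        # clamp away one-ulp excursions of the interpolation arithmetic
        p = np.clip(
            fire.p_max + (fire.p_min - fire.p_max) * frac, fire.p_min, fire.p_max
        )
    return float(p) if np.isscalar(C) or np.ndim(C) == 0 else p


def effective_cover(x, fire: FireProbabilityModel) -> float:
    """Cover total over the classes in ``fire.cover_mask`` (all if None)."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if fire.cover_mask is None:
        return float(arr.sum())
    idx = np.asarray(fire.cover_mask, dtype=int) - 1
    if idx.max() >= arr.size:
        raise ConfigurationError(
            f"cover_mask index {idx.max() + 1} out of range for n={arr.size}"
        )
    return float(arr[idx].sum())


def effective_update_matrix(config: ModelConfig, fired: bool) -> np.ndarray:
    """Linear part of the one-year affine map.

    With space-limited recruitment the map is x -> M x + a e1 with
    M = (I - a e1 1') A; with constant recruitment M = A.
    """
    A = config.matrix(fired)
    if not config.recruitment.space_limited:
        return A.copy()
    n = config.n
    M = A.copy()
    M[0, :] -= config.recruitment.a * A.sum(axis=0)
    return M


def step(x, fired: bool, config: ModelConfig) -> np.ndarray:
    """Advance the state one year under the given fire status.

    Survival/transition first (``A_f`` if ``fired`` else ``A_nf``), then
    recruitment into class 1.  Raises :class:`SimplexError` if the result
    leaves the simplex by more than the clipping tolerance, which can only
    happen for invalid matrices or constant recruitment.
    """
    arr = validate_state(x, config.n)
    xp = config.matrix(fired) @ arr
    a = config.recruitment.a
    if config.recruitment.space_limited:
        b = a * (1.0 - xp.sum())
    else:
        b = a
    xp[0] += b
    total = xp.sum()
    if np.any(xp < -CLIP_TOL) or total > 1 + CLIP_TOL:
        raise SimplexError(
            f"step left the simplex (total={total:.6g}); check column sums / recruitment"
        )
    return np.clip(xp, 0.0, 1.0)


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of a stochastic (or forced) simulation.

    ``states`` has shape (horizon+1, n); ``fires[t]`` is the Bernoulli fire
    indicator drawn from the fire probability at the *pre-update* state
    ``states[t]`` (the fuel that carries a fire exists before that year's
    mortality).
    """

    states: np.ndarray
    fires: np.ndarray
    config: ModelConfig

    @property
    def horizon(self) -> int:
        return self.fires.size

    @property
    def total_cover(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def effective_cover(self) -> np.ndarray:
        fire = self.config.fire
        if fire.cover_mask is None:
            return self.total_cover
        idx = np.asarray(fire.cover_mask, dtype=int) - 1
        return self.states[:, idx].sum(axis=1)


def _simulate_scalar(
    config: ModelConfig,
    x0: float,
    horizon: int,
    forced_fire: bool | None,
    rng: np.random.Generator,
) -> SimulationResult:
    """Fast path for the single-class model (plain-float inner loop)."""
    alpha_nf = float(config.stages.A_nf[0, 0])
    alpha_f = float(config.stages.A_f[0, 0])
    a = config.recruitment.a
    f = config.fire
    th1, th2, pmax, pmin = f.theta1, f.theta2, f.p_max, f.p_min
    slope = (pmin - pmax) / (th2 - th1) if th2 > th1 else 0.0
    states = np.empty(horizon + 1)
    fires = np.empty(horizon, dtype=np.int8)
    u = rng.random(horizon) if forced_fire is None else None
    x = x0
    states[0] = x
    for t in range(horizon):
        if forced_fire is None:
            if x <= th1:
                p = pmax
            elif x >= th2:
                p = pmin
            else:
                p = pmax + slope * (x - th1)
            fired = u[t] < p
        else:
            fired = forced_fire
        xp = (alpha_f if fired else alpha_nf) * x
        x = xp + a * (1.0 - xp)
        fires[t] = fired
        states[t + 1] = x
    return SimulationResult(states.reshape(-1, 1), fires, config)


def simulate(
    config: ModelConfig,
    x0,
    horizon: int,
    forced_fire: bool | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Simulate the switched dynamics for ``horizon`` years.

    Each year the fire indicator is drawn from the fire probability evaluated
    at the current (pre-update) effective cover, using the generator seeded
    from ``config.seed`` (or the supplied ``rng``); ``forced_fire`` pins the
    dynamic instead.  Deterministic given (config, seed, x0, horizon).
    """
    if horizon < 1:
        raise ConfigurationError(f"horizon must be >= 1, got {horizon}")
    x = validate_state(x0, config.n)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n == 1 and config.recruitment.space_limited and (
        config.fire.cover_mask in (None, (1,))
    ):
        return _simulate_scalar(config, float(x[0]), horizon, forced_fire, rng)

    states = np.empty((horizon + 1, config.n))
    fires = np.empty(horizon, dtype=np.int8)
    states[0] = x
    u = rng.random(horizon) if forced_fire is None else None
    for t in range(horizon):
        if forced_fire is None:
            p = fire_probability(effective_cover(x, config.fire), config.fire)
            fired = bool(u[t] < p)
        else:
            fired = bool(forced_fire)
        x = step(x, fired, config)
        fires[t] = fired
        states[t + 1] = x
    return SimulationResult(states, fires, config)


def steady_state(config: ModelConfig, which: str) -> np.ndarray:
    """Fixed point of the one-year map under a constant dynamic.

    ``which`` is ``"no_fire"`` (undisturbed steady state) or ``"fire"``
    (disturbed).  Closed form x* = (I - M)^-1 a e1 with M the effective update
    matrix; raises :class:`UnstableDynamicsError` when the dynamic does not
    contract (spectral radius >= 1).
    """
    if which not in ("no_fire", "fire"):
        raise ValueError(f"which must be 'no_fire' or 'fire', got {which!r}")
    M = effective_update_matrix(config, fired=(which == "fire"))
    rho = max(abs(np.linalg.eigvals(M)))
    if rho >= 1 - 1e-12:
        raise UnstableDynamicsError(
            f"{which} dynamic has spectral radius {rho:.6g} >= 1: no attracting steady state"
        )
    b = np.zeros(config.n)
    b[0] = config.recruitment.a
    x_star = np.linalg.solve(np.eye(config.n) - M, b)
    return validate_state(x_star, config.n, tol=CLIP_TOL)


@dataclass(frozen=True)
class SteadyStates:
    """Both steady states with the fire probability evaluated at each."""

    x_star_nf: np.ndarray
    x_star_f: np.ndarray
    p_at_nf: float
    p_at_f: float


def steady_states(config: ModelConfig) -> SteadyStates:
    x_nf = steady_state(config, "no_fire")
    x_f = steady_state(config, "fire")
    return SteadyStates(
        x_star_nf=x_nf,
        x_star_f=x_f,
        p_at_nf=fire_probability(effective_cover(x_nf, config.fire), config.fire),
        p_at_f=fire_probability(effective_cover(x_f, config.fire), config.fire),
    )


@dataclass(frozen=True)
class StabilityReport:
    """Sufficient-stability diagnostics for the two effective update maps.

    ``one_norm_*`` is the induced 1-norm (maximum column sum) of the effective
    update matrix; ``scaled_max_norm_*`` is n times its maximum absolute
    element, which upper-bounds the induced 1-norm.  ``stable_* = one_norm < 1``
    guarantees that every switched product of the two maps contracts in the
    1-norm, hence the whole switched system is asymptotically stable.
    """

    stable_nf: bool
    stable_f: bool
    one_norm_nf: float
    one_norm_f: float
    scaled_max_norm_nf: float
    scaled_max_norm_f: float


def stability_check(config: ModelConfig) -> StabilityReport:
    """Check the sufficient contraction condition for both dynamics."""
    norms = {}
    for key, fired in (("nf", False), ("f", True)):
        M = effective_update_matrix(config, fired)
        norms["one_norm_" + key] = float(np.abs(M).sum(axis=0).max())
        norms["scaled_max_norm_" + key] = float(config.n * np.abs(M).max())
    return StabilityReport(
        stable_nf=norms["one_norm_nf"] < 1.0,
        stable_f=norms["one_norm_f"] < 1.0,
        **norms,
    )


def invert_fire_thresholds(
    p_at_nf_target: float, p_at_f_target: float, config: ModelConfig
) -> tuple[float, float]:
    """Solve for (theta1, theta2) pinning the fire probability at both steady states.

    In the p_max=1, p_min=0 regime the linear branch of p(C) through the two
    points (C*_nf, p_nf) and (C*_f, p_f) gives

        theta2 - theta1 = (C*_nf - C*_f) / (p_f - p_nf)
        theta2          = C*_nf + p_nf * (theta2 - theta1)

    Raises :class:`ConfigurationError` when targets are degenerate or the
    solution escapes [0, 1] (the point lies outside the feasible triangle).
    """
    p_nf, p_f = float(p_at_nf_target), float(p_at_f_target)
    if not (config.fire.p_max == 1.0 and config.fire.p_min == 0.0):
        raise ConfigurationError("threshold inversion requires p_max=1, p_min=0")
    if not (0.0 < p_nf < 1.0 and 0.0 < p_f < 1.0):
        raise ConfigurationError("target probabilities must lie strictly in (0, 1)")
    if p_f <= p_nf:
        raise ConfigurationError(
            f"need p_at_f > p_at_nf (degenerate slope otherwise), got {p_f} <= {p_nf}"
        )
    ss = steady_states(config)
    c_nf = effective_cover(ss.x_star_nf, config.fire)
    c_f = effective_cover(ss.x_star_f, config.fire)
    if c_nf <= c_f:
        raise ConfigurationError(
            f"undisturbed cover {c_nf:.6g} must exceed disturbed cover {c_f:.6g}"
        )
    width = (c_nf - c_f) / (p_f - p_nf)
    theta2 = c_nf + p_nf * width
    theta1 = theta2 - width
    if not (0.0 <= theta1 <= theta2 <= 1.0):
        raise ConfigurationError(
            f"targets infeasible: thresholds ({theta1:.6g}, {theta2:.6g}) escape [0, 1]"
        )
    return theta1, theta2
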