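"""Reference configurations and random configuration sampling.

The scalar reference configuration is the package's standard worked example:
one size class with no-fire retention 0.9, fire retention 0.4, recruitment
0.1 and fire thresholds (0.2, 0.8).  The three-class matrices and the
ensemble sampling bands are synthetic stand-ins chosen to be demographically
plausible (see docs/methods.md); they are package defaults, not field
estimates.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    FireProbabilityModel,
    ModelConfig,
    Recruitment,
    StagePair,
    invert_fire_thresholds,
)

__all__ = [
    "scalar_config",
    "scalar_reference_config",
    "scalar_fast_growth_config",
    "scalar_bimodal_config",
    "three_class_reference_config",
    "random_valid_config",
]


def scalar_config(
    alpha_nf: float,
    alpha_f: float,
    a: float,
    theta1: float,
    theta2: float,
    p_max: float = 1.0,
    p_min: float = 0.0,
    seed: int = 0,
    space_limited: bool = True,
) -> ModelConfig:
    """Single-size-class configuration from its five scalar parameters."""
    return ModelConfig(
        stages=StagePair(A_nf=[[alpha_nf]], A_f=[[alpha_f]]),
        recruitment=Recruitment(a=a, space_limited=space_limited),
        fire=FireProbabilityModel(theta1=theta1, theta2=theta2, p_max=p_max, p_min=p_min),
        seed=seed,
    )


def scalar_reference_config(seed: int = 0) -> ModelConfig:
    """The scalar reference configuration (retentions 0.9/0.4, a=0.1, thresholds 0.2/0.8)."""
    return scalar_config(0.9, 0.4, 0.1, 0.2, 0.8, seed=seed)


def scalar_fast_growth_config(seed: int = 0) -> ModelConfig:
    """Fast-growth, fire-vulnerable demography (retentions 0.9/0.05, a=0.45).

    Both dynamics contract strongly toward their steady states (undisturbed
    cover 0.89, disturbed 0.46), the precondition for switching-induced
    bimodality: transitions between the two regimes complete in a few years,
    so neither regime's approach path is disproportionately exposed to the
    other dynamic.  Slow-growing demographies (small recruitment) cannot
    produce bimodality at all — the climb back to high cover spends too many
    years at fire-prone intermediate covers.
    """
    return scalar_config(0.9, 0.05, 0.45, 0.2, 0.8, seed=seed)


def scalar_bimodal_config(
    seed: int = 0, p_at_nf: float = 0.05, p_at_f: float = 0.9
) -> ModelConfig:
    """A scalar configuration with a genuinely bimodal cover distribution.

    Fast-growth demography with thresholds inverted so both steady states
    have a low risk of being left: fire probability ``p_at_nf`` at the
    undisturbed steady state and ``p_at_f`` at the disturbed one.  Long
    sojourns in each dynamic, with quick transitions, produce a two-peaked
    stationary distribution (bimodality index about 0.15 at the defaults).
    """
    base = scalar_fast_growth_config(seed)
    theta1, theta2 = invert_fire_thresholds(p_at_nf, p_at_f, base)
    alpha_nf = float(base.stages.A_nf[0, 0])
    alpha_f = float(base.stages.A_f[0, 0])
    return scalar_config(alpha_nf, alpha_f, base.recruitment.a, theta1, theta2, seed=seed)


def three_class_reference_config(seed: int = 0) -> ModelConfig:
    """Synthetic three-size-class configuration (small/medium/large trees).

    Stage matrices are package-chosen stand-ins with the usual Lefkovitch
    structure (stay on the diagonal, growth on the subdiagonal).  Without
    fire, trees advance quickly through the classes; with fire, small trees
    are mostly killed and the canopy classes are knocked back (top-kill).
    Both dynamics contract fast, the same precondition for bimodality as in
    the scalar case.  The fire feedback — and the vegetation cover itself —
    is carried by the last two classes only, small trees (< 1 m) contributing
    negligibly to the canopy.  Thresholds are inverted so the fire
    probability is 0.05 at the undisturbed canopy cover (0.56) and 0.95 at
    the disturbed one (0.10): both regimes are sticky, fires cluster, and
    the stationary canopy-cover distribution is bimodal (B about 0.15).
    """
    A_nf = [
        [0.30, 0.00, 0.00],
        [0.55, 0.50, 0.00],
        [0.00, 0.45, 0.60],
    ]
    A_f = [
        [0.05, 0.00, 0.00],
        [0.10, 0.40, 0.00],
        [0.00, 0.20, 0.55],
    ]
    provisional = ModelConfig(
        stages=StagePair(A_nf=A_nf, A_f=A_f),
        recruitment=Recruitment(a=0.45),
        fire=FireProbabilityModel(theta1=0.1, theta2=0.9, cover_mask=(2, 3)),
        seed=seed,
    )
    theta1, theta2 = invert_fire_thresholds(0.05, 0.95, provisional)
    return ModelConfig(
        stages=provisional.stages,
        recruitment=provisional.recruitment,
        fire=FireProbabilityModel(theta1=theta1, theta2=theta2, cover_mask=(2, 3)),
        seed=seed,
    )


def random_valid_config(
    rng: np.random.Generator,
    n: int = 1,
    max_col_sum: float = 1.0,
    a_range: tuple[float, float] = (0.05, 0.3),
) -> ModelConfig:
    """Draw a random valid configuration with Lefkovitch-structured matrices.

    Column j of each matrix splits a survival total (uniform on
    [0, max_col_sum]) between staying in class j and advancing to class j+1;
    the fire matrix entries are scaled down from the no-fire ones by a random
    per-class burn survival factor.  Thresholds and recruitment are drawn
    uniformly from their valid domains.  Intended for property tests and
    stress sweeps, not as an ecological prior.
    """
    A_nf = np.zeros((n, n))
    A_f = np.zeros((n, n))
    for j in range(n):
        total = rng.uniform(0.0, max_col_sum)
        stay_frac = rng.uniform(0.0, 1.0)
        A_nf[j, j] = total * stay_frac
        if j + 1 < n:
            A_nf[j + 1, j] = total * (1.0 - stay_frac)
        burn_survival = rng.uniform(0.0, 1.0)
        A_f[:, j] = A_nf[:, j] * burn_survival
    theta = np.sort(rng.uniform(0.0, 1.0, size=2))
    p = np.sort(rng.uniform(0.0, 1.0, size=2))
    return ModelConfig(
        stages=StagePair(A_nf=A_nf, A_f=A_f),
        recruitment=Recruitment(a=rng.uniform(*a_range)),
        fire=FireProbabilityModel(
            theta1=float(theta[0]),
            theta2=float(theta[1]),
            p_max=float(p[1]),
            p_min=float(p[0]),
        ),
        seed=int(rng.integers(2**31 - 1)),
    )
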