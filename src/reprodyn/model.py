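"""Rate expressions for reproductive interference with absolute density dependence.

The generalized model derives the birth-rate reduction of species *i* from
encounter mechanics: heterospecific males follow a type II functional
response, so the per-female rate of heterospecific mating attempts saturates
with handling time and is diluted by females of both species.  The resulting
per-capita interference term depends on the *absolute* densities, not only
the species ratio — interference is weaker when the community is sparse.

The conventional model keeps the classical frequency-dependent term
``s_i N_i / (s_i N_i + i_ij s_j N_j)``, which is invariant under a joint
rescaling of both densities.

Continuous dynamics (per species, focal index *i*, interferer *j*)::

    dN_i/dt = N_i [ (1 - s_i) B_i(N_i, N_j) - D_i - H_i N_i ]

with the generalized birth rate

    B_i = B_i0 exp( - a_ij s_j N_j / S / (1 + {b_ij (1-s_i) N_i
                                              + b_jj (1-s_j) N_j} / S) )

or the conventional per-capita fertilization share

    B_i = B_i0 s_i N_i / (s_i N_i + i_ij s_j N_j).

Discrete-generation analogues (sex ratios 1/2 focal, all-male interferers)
are provided for fitting single-generation fecundity data.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    CommunitySpec,
    GeneralizedRIParams,
    MechanisticComponents,
    SpeciesParams,
)

__all__ = [
    "compose_interaction",
    "interaction_rate",
    "birth_rate",
    "birth_rate_conventional",
    "growth_rate_generalized",
    "growth_rate_conventional",
    "growth_rate",
    "two_sex_rates",
    "discrete_step_generalized",
    "discrete_step_conventional",
]


def _require_finite(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


def compose_interaction(mech: MechanisticComponents) -> GeneralizedRIParams:
    """Reduce behavioural components to the three interference parameters.

    a = alpha * e_ij (interference efficiency), b_ij = e_ij * h_ij and
    b_jj = e_jj * h_jj (dilution coefficients).
    """
    return GeneralizedRIParams(
        a=mech.alpha * mech.e_ij,
        b_ij=mech.e_ij * mech.h_ij,
        b_jj=mech.e_jj * mech.h_jj,
    )


def interaction_rate(
    mech: MechanisticComponents,
    species_i: SpeciesParams,
    species_j: SpeciesParams,
    N_i: float,
    N_j: float,
    S: float,
) -> float:
    """Per-female rate of heterospecific mating attempts (type II response).

    I_ij = (e_ij s_j N_j / S) /
           (1 + e_ij h_ij (1 - s_i) N_i / S + e_jj h_jj (1 - s_j) N_j / S)
    """
    _require_finite(N_i=N_i, N_j=N_j, S=S)
    if S <= 0:
        raise ValueError("habitat area S must be > 0")
    if N_i < 0 or N_j < 0:
        raise ValueError("densities must be >= 0")
    numer = mech.e_ij * species_j.s * N_j / S
    denom = (
        1.0
        + mech.e_ij * mech.h_ij * (1.0 - species_i.s) * N_i / S
        + mech.e_jj * mech.h_jj * (1.0 - species_j.s) * N_j / S
    )
    return numer / denom


def birth_rate(
    species_i: SpeciesParams,
    gi: GeneralizedRIParams,
    N_i: float,
    N_j: float,
    s_j: float,
    S: float,
) -> float:
    """Generalized birth rate of species i under interference by species j.

    Exponential decay of fecundity with the per-female interaction rate:
    B = B0 exp(-a s_j N_j / S / (1 + {b_ij (1-s_i) N_i + b_jj (1-s_j) N_j}/S)).
    Always in (0, B0].
    """
    _require_finite(N_i=N_i, N_j=N_j, S=S)
    denom = 1.0 + (gi.b_ij * (1.0 - species_i.s) * N_i + gi.b_jj * (1.0 - s_j) * N_j) / S
    exponent = -(gi.a * s_j * N_j / S) / denom
    return species_i.B0 * math.exp(exponent)


def birth_rate_conventional(
    species_i: SpeciesParams,
    i_ij: float,
    N_i: float,
    N_j: float,
    s_j: float,
) -> float:
    """Frequency-dependent birth rate B0 * s_i N_i / (s_i N_i + i s_j N_j).

    Returns 0 at (0, 0): the removable singularity is resolved by the
    convention that an extinct population stays extinct.
    """
    _require_finite(N_i=N_i, N_j=N_j)
    own = species_i.s * N_i
    other = i_ij * s_j * N_j
    if own == 0.0 and other == 0.0:
        return 0.0
    return species_i.B0 * own / (own + other)


def growth_rate_generalized(spec: CommunitySpec, N1: float, N2: float, focal: int) -> float:
    """dN_focal/dt for the generalized (encounter-rate) model."""
    if spec.family != "generalized":
        raise ValueError("growth_rate_generalized requires a generalized-family spec")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    N_i = (N1, N2)[focal]
    N_j = (N1, N2)[1 - focal]
    if N_i == 0.0:
        return 0.0
    B = birth_rate(sp, spec.interaction(focal), N_i, N_j, other.s, spec.S)
    return N_i * ((1.0 - sp.s) * B - sp.D - sp.H * N_i)


def growth_rate_conventional(spec: CommunitySpec, N1: float, N2: float, focal: int) -> float:
    """dN_focal/dt for the conventional (frequency-dependent) model."""
    if spec.family != "conventional":
        raise ValueError("growth_rate_conventional requires a conventional-family spec")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    N_i = (N1, N2)[focal]
    N_j = (N1, N2)[1 - focal]
    if N_i == 0.0:
        return 0.0
    B = birth_rate_conventional(sp, spec.interaction(focal).i, N_i, N_j, other.s)
    return N_i * ((1.0 - sp.s) * B - sp.D - sp.H * N_i)


def growth_rate(spec: CommunitySpec, N1: float, N2: float, focal: int) -> float:
    """dN_focal/dt, dispatching on the spec's model family."""
    if spec.family == "generalized":
        return growth_rate_generalized(spec, N1, N2, focal)
    return growth_rate_conventional(spec, N1, N2, focal)


def two_sex_rates(
    spec: CommunitySpec,
    F1: float,
    M1: float,
    F2: float,
    M2: float,
    focal: int,
) -> tuple[float, float]:
    """(dF/dt, dM/dt) for the focal species in the two-sex formulation.

    Females are the reproducing class; newborns are allocated to the sexes at
    the fixed ratio s.  Both sexes share mortality D and crowding H (N = F+M).
    At the consistent split F = (1-s) N, M = s N the two equations sum to the
    single-equation total-density dynamics.
    """
    _require_finite(F1=F1, M1=M1, F2=F2, M2=M2)
    if min(F1, M1, F2, M2) < 0:
        raise ValueError("sex-specific densities must be >= 0")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    F_i, M_i = (F1, F2)[focal], (M1, M2)[focal]
    N_i = F_i + M_i
    N_j = (F2 + M2, F1 + M1)[focal]
    if spec.family == "generalized":
        B = birth_rate(sp, spec.interaction(focal), N_i, N_j, other.s, spec.S)
    else:
        B = birth_rate_conventional(sp, spec.interaction(focal).i, N_i, N_j, other.s)
    dF = F_i * ((1.0 - sp.s) * B - sp.D - sp.H * N_i)
    dM = F_i * sp.s * B - M_i * (sp.D + sp.H * N_i)
    return dF, dM


def discrete_step_generalized(
    R: float,
    a: float,
    b: float,
    H: float,
    S: float,
    N_i: float,
    N_j: float,
) -> float:
    """One generation of the discrete generalized map.

    N' = N [ (R/2) exp( -(a N_j / S) / (1 + b N_i / (2 S)) ) - H N ].

    Assumes an equal focal sex ratio (females = N/2) and all-male
    interferers.  A negative result (possible when H N is large) is clamped
    to 0: densities are non-negative and the clamp only binds outside the
    regime the map is meant for.
    """
    _require_finite(R=R, a=a, b=b, H=H, S=S, N_i=N_i, N_j=N_j)
    if S <= 0:
        raise ValueError("habitat area S must be > 0")
    if N_i == 0.0:
        return 0.0
    mult = 0.5 * R * math.exp(-(a * N_j / S) / (1.0 + b * N_i / (2.0 * S))) - H * N_i
    return max(N_i * mult, 0.0)


def discrete_step_conventional(
    R: float,
    i: float,
    H: float,
    N_i: float,
    N_j: float,
) -> float:
    """One generation of the discrete conventional map.

    N' = N [ (R/2) N / (N + 2 i N_j) - H N ], clamped at 0.
    (0, 0) maps to 0 by the extinct-stays-extinct convention.
    """
    _require_finite(R=R, i=i, H=H, N_i=N_i, N_j=N_j)
    if N_i == 0.0:
        return 0.0
    denom = N_i + 2.0 * i * N_j
    mult = 0.5 * R * N_i / denom - H * N_i
    return max(N_i * mult, 0.0)
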