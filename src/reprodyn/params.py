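"""Parameter containers for two-species reproductive-interference communities.

A community couples two species through directed mating interference: males of
species *j* attempt to mate with females of species *i*, reducing their birth
rate.  Each direction (2→1 and 1→2) carries its own interference parameters,
so asymmetric interactions are the general case; :func:`symmetric_community`
is a convenience for the common symmetric setting.

Two interference families are supported:

* *generalized* — encounter-rate mechanics with a saturating (type II)
  functional response; interference strength depends on absolute density.
* *conventional* — the classical frequency-dependent formulation, where only
  the species ratio matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import yaml

__all__ = [
    "SpeciesParams",
    "MechanisticComponents",
    "GeneralizedRIParams",
    "ConventionalRIParams",
    "CommunitySpec",
    "State",
    "symmetric_community",
]


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SpeciesParams:
    """Demographic constants of one species.

    Parameters
    ----------
    B0 : float
        Intrinsic (interference-free) birth rate per female per unit time.
    s : float
        Sex ratio as the fraction of males, in [0, 1].
    D : float
        Density-independent mortality rate (>= 0).
    H : float
        Coefficient of conspecific density dependence (>= 0).  The
        single-species carrying capacity is ``((1 - s) * B0 - D) / H``.
    """

    B0: float
    s: float
    D: float = 0.0
    H: float = 0.0

    def __post_init__(self) -> None:
        for name in ("B0", "s", "D", "H"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        if self.B0 <= 0:
            raise ValueError(f"B0 must be > 0, got {self.B0}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"sex ratio s must be in [0, 1], got {self.s}")
        if self.D < 0 or self.H < 0:
            raise ValueError("D and H must be >= 0")

    @property
    def low_density_growth(self) -> float:
        """Per-capita growth rate in the absence of any density effects."""
        return (1.0 - self.s) * self.B0 - self.D

    @property
    def carrying_capacity(self) -> float:
        """Single-species equilibrium density; ``inf`` when H == 0."""
        r = self.low_density_growth
        if r <= 0:
            return 0.0
        if self.H == 0:
            return math.inf
        return r / self.H


@dataclass(frozen=True)
class MechanisticComponents:
    """Behavioural components of one directed interference interaction.

    The directed interaction j→i is built from the fitness impact per
    heterospecific encounter (``alpha``), the mate-searching efficiencies of
    species-*j* males towards hetero- and conspecific females (``e_ij``,
    ``e_jj``; units of area per time) and the handling times per encounter
    (``h_ij``, ``h_jj``).  The mate-search period cancels out of the
    encounter-rate expression and is not stored.
    """

    alpha: float
    e_ij: float
    e_jj: float
    h_ij: float = 0.0
    h_jj: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "e_ij", "e_jj", "h_ij", "h_jj"):
            v = _check_finite(name, getattr(self, name))
            object.__setattr__(self, name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class GeneralizedRIParams:
    """Reduced parameters of the encounter-rate interference model.

    ``a`` = alpha * e_ij is the interference efficiency (per-male impact);
    ``b_ij`` = e_ij * h_ij and ``b_jj`` = e_jj * h_jj are the dilution
    coefficients of conspecific and heterospecific females respectively
    (time a male wastes handling each female class).
    """

    a: float
    b_ij: float = 0.0
    b_jj: float = 0.0

    family: Literal["generalized"] = field(default="generalized", init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("a", "b_ij", "b_jj"):
            v = _check_finite(name, getattr(self, name))
            object.__setattr__(self, name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class ConventionalRIParams:
    """Frequency-dependent interference with a single coefficient ``i``."""

    i: float

    family: Literal["conventional"] = field(default="conventional", init=False, repr=False)

    def __post_init__(self) -> None:
        v = _check_finite("i", self.i)
        object.__setattr__(self, "i", v)
        if v < 0:
            raise ValueError(f"i must be >= 0, got {v}")


InteractionParams = Union[GeneralizedRIParams, ConventionalRIParams]


@dataclass(frozen=True)
class State:
    """Densities of the two species, optionally split by sex.

    ``N1``/``N2`` are total densities.  When the two-sex form is used,
    ``F``/``M`` components must be consistent (``F + M == N``).
    """

    N1: float
    N2: float
    F1: float | None = None
    M1: float | None = None
    F2: float | None = None
    M2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "N1", _check_finite("N1", self.N1))
        object.__setattr__(self, "N2", _check_finite("N2", self.N2))
        if self.N1 < 0 or self.N2 < 0:
            raise ValueError("densities must be >= 0")
        sexes = (self.F1, self.M1, self.F2, self.M2)
        if any(v is not None for v in sexes):
            if any(v is None for v in sexes):
                raise ValueError("either all or none of F1, M1, F2, M2 must be given")
            for name in ("F1", "M1", "F2", "M2"):
                v = _check_finite(name, getattr(self, name))
                object.__setattr__(self, name, v)
                if v < 0:
                    raise ValueError(f"{name} must be >= 0")
            if not math.isclose(self.F1 + self.M1, self.N1, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("F1 + M1 must equal N1")
            if not math.isclose(self.F2 + self.M2, self.N2, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("F2 + M2 must equal N2")

    @classmethod
    def from_totals(cls, N1: float, N2: float, spec: "CommunitySpec") -> "State":
        """Split totals into sexes at each species' fixed sex ratio."""
        s1, s2 = spec.species[0].s, spec.species[1].s
        return cls(
            N1=N1, N2=N2,
            F1=(1 - s1) * N1, M1=s1 * N1,
            F2=(1 - s2) * N2, M2=s2 * N2,
        )


@dataclass(frozen=True)
class CommunitySpec:
    """Two species plus both directed interference interactions.

    ``interaction_12`` parameterizes the effect of species 2's males on
    species 1's females; ``interaction_21`` the reverse.  Both must belong to
    the same model family.  ``S`` is the habitat area (generalized family
    only; the conventional family is area-free).
    """

    species: tuple[SpeciesParams, SpeciesParams]
    interaction_12: InteractionParams
    interaction_21: InteractionParams
    S: float = 1.0

    def __post_init__(self) -> None:
        if len(self.species) != 2:
            raise ValueError("exactly two species required")
        if self.interaction_12.family != self.interaction_21.family:
            raise ValueError("both interactions must belong to the same model family")
        object.__setattr__(self, "S", _check_finite("S", self.S))
        if self.S <= 0:
            raise ValueError(f"habitat area S must be > 0, got {self.S}")

    @property
    def family(self) -> str:
        return self.interaction_12.family

    def interaction(self, focal: int) -> InteractionParams:
        """Interference acting ON species ``focal`` (0 or 1)."""
        if focal not in (0, 1):
            raise ValueError("focal must be 0 or 1")
        return self.interaction_12 if focal == 0 else self.interaction_21

    def swapped(self) -> "CommunitySpec":
        """The same community with species indices exchanged."""
        return CommunitySpec(
            species=(self.species[1], self.species[0]),
            interaction_12=self.interaction_21,
            interaction_21=self.interaction_12,
            S=self.S,
        )

    # -- config (de)serialization ------------------------------------------

    def to_dict(self) -> dict:
        def species_d(sp: SpeciesParams) -> dict:
            return {"B0": sp.B0, "s": sp.s, "D": sp.D, "H": sp.H}

        def inter_d(it: InteractionParams) -> dict:
            if isinstance(it, GeneralizedRIParams):
                return {"a": it.a, "b_ij": it.b_ij, "b_jj": it.b_jj}
            return {"i": it.i}

        return {
            "model_family": self.family,
            "species1": species_d(self.species[0]),
            "species2": species_d(self.species[1]),
            "interaction_12": inter_d(self.interaction_12),
            "interaction_21": inter_d(self.interaction_21),
            "S": self.S,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunitySpec":
        family = d["model_family"]
        if family not in ("generalized", "conventional"):
            raise ValueError(f"unknown model_family {family!r}")

        def inter(block: dict) -> InteractionParams:
            if family == "generalized":
                return GeneralizedRIParams(**block)
            return ConventionalRIParams(**block)

        return cls(
            species=(
                SpeciesParams(**d["species1"]),
                SpeciesParams(**d["species2"]),
            ),
            interaction_12=inter(d["interaction_12"]),
            interaction_21=inter(d["interaction_21"]),
            S=float(d.get("S", 1.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunitySpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def symmetric_community(
    species: SpeciesParams,
    interaction: InteractionParams,
    S: float = 1.0,
) -> CommunitySpec:
    """Community where both species and both interaction directions are equal."""
    return CommunitySpec(
        species=(species, species),
        interaction_12=interaction,
        interaction_21=interaction,
        S=S,
    )
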