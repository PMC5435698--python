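"""Synthetic reaction-surface fecundity data with the structure the fitting assumes.

The generator emulates a full-factorial dish experiment: every combination
of 1–10 focal-species pairs and 0–10 heterospecific males (110 density
cells), three replicate dishes per cell (330 rows), with dishes dated over
a 1,166-day window.  Egg totals are drawn from the fitted models' own noise
law — Gaussian around the family mean with variance proportional to the
number of females — so simulated tables exercise exactly the likelihood the
inference module maximizes.

Negative Gaussian draws are truncated at zero (not resampled) and counted;
truncation is rare at realistic noise levels and the count is reported in
``DataFrame.attrs['n_truncated']``.  Egg totals are kept continuous, the
support of the Gaussian model; ``round_eggs=True`` rounds for realism
studies.  An optional augmentation rule adds a fourth replicate to any cell
whose dish produced zero eggs, mirroring a common dish-failure protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FecundityModelParams, mean_fecundity, validate_reaction_surface

__all__ = ["DesignSpec", "make_design", "simulate_dataset", "default_true_params"]

#: per-female variance scale used when none is supplied: sd of 10 eggs for a
#: single-female dish, i.e. a coefficient of variation of ~17% at a mean
#: fecundity of ~58 eggs — a moderate, realistic dispersion for seed-beetle
#: fecundity counts
DEFAULT_SIGMA2 = 100.0


def default_true_params(
    family: str = "generalized", sigma2: float = DEFAULT_SIGMA2
) -> FecundityModelParams:
    """Reference parameter sets for simulation studies.

    These are the fitted values for the *C. maculatus* / *C. chinensis*
    dish experiment: (R0, a, b, c) = (58.3, 0.119, 0.275, 0.0162) for the
    encounter-rate family and (R0, i, c) = (57.4, 0.272, 0.0156) for the
    frequency-dependent family.
    """
    if family == "generalized":
        return FecundityModelParams(
            family="generalized", R0=58.3, c=0.0162, a=0.119, b=0.275, sigma2=sigma2
        )
    if family == "conventional":
        return FecundityModelParams(
            family="conventional", R0=57.4, c=0.0156, i=0.272, sigma2=sigma2
        )
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of a reaction-surface experiment.

    pairs_range / het_males_range are inclusive (lo, hi) integer ranges;
    date_assignment is "uniform" (each dish dated uniformly at random over
    the window) or "sorted" (replicate batches spread in order over the
    window, mimicking a multi-year experiment run in blocks).
    """

    pairs_range: tuple[int, int] = (1, 10)
    het_males_range: tuple[int, int] = (0, 10)
    n_replicates: int = 3
    date_window_days: int = 1166
    date_assignment: str = "uniform"

    def __post_init__(self) -> None:
        if self.pairs_range[0] > self.pairs_range[1] or self.pairs_range[0] < 1:
            raise ValueError("pairs_range must be a non-empty range with lo >= 1")
        if self.het_males_range[0] > self.het_males_range[1] or self.het_males_range[0] < 0:
            raise ValueError("het_males_range must be a non-empty range with lo >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.date_window_days <= 0:
            raise ValueError("date_window_days must be > 0")
        if self.date_assignment not in ("uniform", "sorted"):
            raise ValueError("date_assignment must be 'uniform' or 'sorted'")

    @property
    def n_cells(self) -> int:
        return (self.pairs_range[1] - self.pairs_range[0] + 1) * (
            self.het_males_range[1] - self.het_males_range[0] + 1
        )

    @property
    def n_rows(self) -> int:
        return self.n_cells * self.n_replicates


def make_design(spec: DesignSpec = DesignSpec(), seed: int | None = 0) -> pd.DataFrame:
    """Lay out the factorial grid of dishes with dates but no egg counts yet."""
    cells = list(
        itertools.product(
            range(spec.pairs_range[0], spec.pairs_range[1] + 1),
            range(spec.het_males_range[0], spec.het_males_range[1] + 1),
        )
    )
    rows = [
        (pairs, males, rep)
        for (pairs, males) in cells
        for rep in range(1, spec.n_replicates + 1)
    ]
    df = pd.DataFrame(rows, columns=["n_pairs", "n_het_males", "replicate_id"])
    n = len(df)
    if spec.date_assignment == "uniform":
        rng = np.random.default_rng(seed)
        df["date_day"] = rng.integers(0, spec.date_window_days + 1, size=n)
    else:  # sorted: replicate batches spread evenly across the window
        order = df.sort_values(["replicate_id", "n_pairs", "n_het_males"]).index
        days = np.floor(np.linspace(0, spec.date_window_days, n)).astype(int)
        df.loc[order, "date_day"] = days
        df["date_day"] = df["date_day"].astype(int)
    df["total_eggs"] = np.nan
    return df[["date_day", "n_pairs", "n_het_males", "total_eggs", "replicate_id"]]


def simulate_dataset(
    design: pd.DataFrame,
    true_params: FecundityModelParams,
    seed: int,
    zero_replicate_rule: bool = False,
    round_eggs: bool = False,
) -> pd.DataFrame:
    """Draw egg totals for every dish in the design.

    total_eggs ~ Normal(mean_fn(row), sigma2 * n_pairs), truncated at 0.
    Deterministic per seed.  With ``zero_replicate_rule=True``, any cell
    containing a zero-egg dish gains one extra replicate of that cell
    (drawn with the same noise law), as a dish-failure protocol would.
    """
    if true_params.sigma2 is None:
        raise ValueError("true_params.sigma2 must be set to simulate")
    df = design.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    mu = mean_fecundity(df, true_params)
    sd = np.sqrt(true_params.sigma2 * df["n_pairs"].to_numpy(float))
    draws = rng.normal(mu, sd)
    n_truncated = int(np.sum(draws < 0))
    df["total_eggs"] = np.maximum(draws, 0.0)

    if zero_replicate_rule:
        zero_rows = df[df["total_eggs"] == 0.0]
        extras = []
        for _, row in zero_rows.iterrows():
            extra = row.copy()
            extra["replicate_id"] = int(df["replicate_id"].max()) + 1
            mu_x = mean_fecundity(pd.DataFrame([extra]), true_params)[0]
            draw = rng.normal(mu_x, np.sqrt(true_params.sigma2 * extra["n_pairs"]))
            if draw < 0:
                n_truncated += 1
            extra["total_eggs"] = max(draw, 0.0)
            extras.append(extra)
        if extras:
            df = pd.concat([df, pd.DataFrame(extras)], ignore_index=True)

    if round_eggs:
        df["total_eggs"] = np.round(df["total_eggs"])
    df.attrs["n_truncated"] = n_truncated
    df.attrs["seed"] = seed
    df.attrs["family"] = true_params.family
    return validate_reaction_surface(df)
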