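"""Maximum-likelihood fitting of single-generation fecundity maps to reaction-surface data.

The data are dishes crossing 1–10 focal-species pairs (equal females and
males, so total focal density N_i = 2 * n_pairs) with 0–10 heterospecific
males (N_j = n_het_males), observed over a multi-year window.  Total egg
output per dish is modelled as Gaussian with mean given by the discrete
one-generation map (conspecific density dependence switched off, H = 0) and
variance proportional to the number of females:

    y_k ~ Normal(mu_k, sigma2 * n_pairs_k)

Generalized mean (encounter-rate interference; focal sex ratio 1/2,
interferers all male, habitat area S = 1):

    mu = n_pairs * R(d) * exp( -a N_j / (1 + b N_i / 2) )

Conventional mean (frequency dependence only):

    mu = n_pairs * R(d) * N_i / (N_i + 2 i N_j)

with a linear date drift R(d) = R0 + c d.  sigma2 is profiled out of the
likelihood in closed form and counted as an estimated parameter, giving
k = 5 (generalized) and k = 4 (conventional) for AIC and residual degrees
of freedom n - 5 for the model comparison.

The two families are compared by AIC and by an extra-sum-of-squares F
statistic on the weighted residuals (y - mu) / sqrt(n_pairs) with one
numerator degree of freedom — the families differ by one mean parameter.
They are not strictly nested; the F form is a reporting convention, not a
claim of exact nesting (a chi-square likelihood-ratio variant is available).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "REQUIRED_COLUMNS",
    "FecundityModelParams",
    "FitResult",
    "load_reaction_surface",
    "validate_reaction_surface",
    "mean_fecundity_generalized",
    "mean_fecundity_conventional",
    "mean_fecundity",
    "negative_log_likelihood",
    "profiled_sigma2",
    "fit",
    "aic",
    "lrt_f",
    "lrt_chi2",
    "compare_families",
    "predict_per_female",
]

REQUIRED_COLUMNS = ("date_day", "n_pairs", "n_het_males", "total_eggs", "replicate_id")

#: median experiment date used for prediction curves
DEFAULT_PREDICTION_DAY = 230.0

_PENALTY = 1e10


def validate_reaction_surface(df: pd.DataFrame) -> pd.DataFrame:
    """Check the reaction-surface column contract and value ranges."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing reaction-surface columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty reaction-surface table")
    if (df["n_pairs"] < 1).any():
        raise ValueError("n_pairs must be >= 1")
    if (df["n_het_males"] < 0).any():
        raise ValueError("n_het_males must be >= 0")
    eggs = df["total_eggs"]
    if eggs.notna().any() and (eggs.dropna() < 0).any():
        raise ValueError("total_eggs must be >= 0")
    if (df["date_day"] < 0).any():
        raise ValueError("date_day must be >= 0")
    return df


def load_reaction_surface(path: str | Path) -> pd.DataFrame:
    """Read a reaction-surface CSV (columns: date_day, n_pairs, n_het_males,
    total_eggs, replicate_id)."""
    return validate_reaction_surface(pd.read_csv(path))


@dataclass(frozen=True)
class FecundityModelParams:
    """Parameters of one fecundity model family.

    R0: initial per-female fecundity (eggs); c: date drift (eggs/day);
    a, b: interference efficiency and conspecific dilution (generalized);
    i: interference coefficient (conventional); sigma2: per-female variance.
    """

    family: Literal["generalized", "conventional"]
    R0: float
    c: float = 0.0
    a: float | None = None
    b: float | None = None
    i: float | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be > 0")
        if self.family == "generalized":
            if self.a is None or self.b is None:
                raise ValueError("generalized family requires a and b")
            if self.a < 0 or self.b < 0:
                raise ValueError("a and b must be >= 0")
        elif self.family == "conventional":
            if self.i is None:
                raise ValueError("conventional family requires i")
            if self.i < 0:
                raise ValueError("i must be >= 0")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def mean_params(self) -> tuple[float, ...]:
        if self.family == "generalized":
            return (self.R0, self.c, self.a, self.b)
        return (self.R0, self.c, self.i)

    @property
    def n_params(self) -> int:
        """Estimated-parameter count including sigma2."""
        return len(self.mean_params) + 1

    def to_dict(self) -> dict:
        d = {"family": self.family, "R0": self.R0, "c": self.c, "sigma2": self.sigma2}
        if self.family == "generalized":
            d.update(a=self.a, b=self.b)
        else:
            d.update(i=self.i)
        return d


def mean_fecundity_generalized(
    df: pd.DataFrame, R0: float, c: float, a: float, b: float, S: float = 1.0
) -> np.ndarray:
    """Expected total eggs per dish under the encounter-rate map."""
    d = df["date_day"].to_numpy(float)
    pairs = df["n_pairs"].to_numpy(float)
    N_i = 2.0 * pairs
    N_j = df["n_het_males"].to_numpy(float)
    R = R0 + c * d
    return pairs * R * np.exp(-(a * N_j / S) / (1.0 + b * N_i / (2.0 * S)))


def mean_fecundity_conventional(
    df: pd.DataFrame, R0: float, c: float, i: float
) -> np.ndarray:
    """Expected total eggs per dish under the frequency-dependent map."""
    d = df["date_day"].to_numpy(float)
    pairs = df["n_pairs"].to_numpy(float)
    N_i = 2.0 * pairs
    N_j = df["n_het_males"].to_numpy(float)
    R = R0 + c * d
    return pairs * R * N_i / (N_i + 2.0 * i * N_j)


def mean_fecundity(df: pd.DataFrame, params: FecundityModelParams, S: float = 1.0) -> np.ndarray:
    if params.family == "generalized":
        return mean_fecundity_generalized(df, params.R0, params.c, params.a, params.b, S=S)
    return mean_fecundity_conventional(df, params.R0, params.c, params.i)


def negative_log_likelihood(
    df: pd.DataFrame, params: FecundityModelParams, sigma2: float | None = None
) -> float:
    """Gaussian negative log-likelihood with Var(y_k) = sigma2 * n_pairs_k."""
    s2 = params.sigma2 if sigma2 is None else sigma2
    if s2 is None or s2 <= 0:
        raise ValueError("sigma2 must be supplied and > 0")
    y = df["total_eggs"].to_numpy(float)
    F = df["n_pairs"].to_numpy(float)
    mu = mean_fecundity(df, params)
    var = s2 * F
    return float(np.sum(0.5 * np.log(2.0 * math.pi * var) + (y - mu) ** 2 / (2.0 * var)))


def profiled_sigma2(y: np.ndarray, mu: np.ndarray, F: np.ndarray) -> float:
    """Closed-form MLE of the variance scale: mean of (y-mu)^2 / n_pairs."""
    return float(np.mean((y - mu) ** 2 / F))


def weighted_rss(df: pd.DataFrame, params: FecundityModelParams) -> float:
    """Sum of squared weighted residuals (y - mu)^2 / n_pairs."""
    y = df["total_eggs"].to_numpy(float)
    F = df["n_pairs"].to_numpy(float)
    mu = mean_fecundity(df, params)
    return float(np.sum((y - mu) ** 2 / F))


@dataclass(frozen=True)
class FitResult:
    """A converged maximum-likelihood fit of one model family."""

    params: FecundityModelParams
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    weighted_rss: float
    converged: bool
    n_starts_used: int
    diagnostics: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "family": self.params.family,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "k": self.n_params,
            "wrss": self.weighted_rss,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _profiled_nll_factory(
    df: pd.DataFrame, family: str
) -> tuple[Callable[[np.ndarray], float], np.ndarray, np.ndarray, np.ndarray]:
    y = df["total_eggs"].to_numpy(float)
    F = df["n_pairs"].to_numpy(float)
    d = df["date_day"].to_numpy(float)
    pairs = F
    N_i = 2.0 * pairs
    N_j = df["n_het_males"].to_numpy(float)
    n = len(y)
    log_F_sum = float(np.sum(np.log(F)))
    const = 0.5 * n * math.log(2.0 * math.pi) + 0.5 * log_F_sum + 0.5 * n

    def nll(theta: np.ndarray) -> float:
        R = theta[0] + theta[1] * d
        if np.any(R <= 0):
            return _PENALTY * (1.0 + float(np.sum(np.minimum(R, 0.0) ** 2)))
        if family == "generalized":
            a, b = theta[2], theta[3]
            mu = pairs * R * np.exp(-(a * N_j) / (1.0 + b * N_i / 2.0))
        else:
            i = theta[2]
            mu = pairs * R * N_i / (N_i + 2.0 * i * N_j)
        s2 = np.mean((y - mu) ** 2 / F)
        if s2 <= 0:
            return -_PENALTY  # exact interpolation; cannot occur with noise
        return const + 0.5 * n * math.log(s2)

    return nll, y, F, d


def _default_bounds(family: str, df: pd.DataFrame) -> list[tuple[float, float]]:
    y = df["total_eggs"].to_numpy(float)
    per_female_max = float(np.max(y / df["n_pairs"].to_numpy(float)))
    R0_hi = max(10.0 * per_female_max, 100.0)
    bounds = [(1e-6, R0_hi), (-1.0, 1.0)]
    if family == "generalized":
        bounds += [(0.0, 50.0), (0.0, 50.0)]
    else:
        bounds += [(0.0, 50.0)]
    return bounds


def _initial_points(
    family: str, df: pd.DataFrame, n_starts: int, rng: np.random.Generator
) -> np.ndarray:
    """Moment-based centre plus seeded log-uniform jitter on the interference axes."""
    baseline = df[df["n_het_males"] == 0]
    if len(baseline):
        R0_guess = float((baseline["total_eggs"] / baseline["n_pairs"]).mean())
    else:
        R0_guess = float((df["total_eggs"] / df["n_pairs"]).mean())
    R0_guess = max(R0_guess, 1.0)
    n_inter = 2 if family == "generalized" else 1
    pts = np.empty((n_starts, 2 + n_inter))
    pts[:, 0] = R0_guess * rng.uniform(0.7, 1.3, size=n_starts)
    pts[:, 1] = rng.normal(0.0, 0.01, size=n_starts)
    pts[:, 2:] = 10.0 ** rng.uniform(-3, 0, size=(n_starts, n_inter))
    pts[0, :2] = (R0_guess, 0.0)  # one undithered moment start
    return pts


def fit(
    df: pd.DataFrame,
    family: Literal["generalized", "conventional"],
    n_starts: int = 20,
    seed: int = 0,
    bounds: list[tuple[float, float]] | None = None,
) -> FitResult:
    """Fit one family by bounded multi-start maximum likelihood.

    sigma2 is profiled analytically inside the objective and reported as
    part of the estimate (and counted in k).  Deterministic given ``seed``.
    """
    validate_reaction_surface(df)
    df = df.dropna(subset=["total_eggs"]).reset_index(drop=True)
    nll, y, F, d = _profiled_nll_factory(df, family)
    n = len(y)
    n_mean_params = 4 if family == "generalized" else 3
    if n < n_mean_params + 1:
        raise ValueError(f"need at least {n_mean_params + 1} rows, got {n}")
    if bounds is None:
        bounds = _default_bounds(family, df)
    rng = np.random.default_rng(seed)
    starts = _initial_points(family, df, n_starts, rng)

    best = None
    n_used = 0
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        n_used += 1
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        if res.success and (best is None or res.fun < best.fun - 1e-12):
            best = res
    if best is None:
        raise RuntimeError(
            f"no optimization start converged for family={family!r} "
            f"(n={n}, n_starts={n_starts})"
        )

    theta = best.x
    if family == "generalized":
        mu = mean_fecundity_generalized(df, theta[0], theta[1], theta[2], theta[3])
        params = FecundityModelParams(
            family="generalized", R0=theta[0], c=theta[1], a=theta[2], b=theta[3],
            sigma2=profiled_sigma2(y, mu, F),
        )
    else:
        mu = mean_fecundity_conventional(df, theta[0], theta[1], theta[2])
        params = FecundityModelParams(
            family="conventional", R0=theta[0], c=theta[1], i=theta[2],
            sigma2=profiled_sigma2(y, mu, F),
        )
    loglik = -negative_log_likelihood(df, params)
    k = params.n_params
    return FitResult(
        params=params,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n_obs=n,
        n_params=k,
        weighted_rss=weighted_rss(df, params),
        converged=bool(best.success),
        n_starts_used=n_used,
        diagnostics={"optimizer": "L-BFGS-B", "nll": float(best.fun), "seed": seed},
    )


def aic(result: FitResult) -> float:
    """Akaike Information Criterion 2k - 2 ln L (k includes sigma2)."""
    return 2.0 * result.n_params - 2.0 * result.loglik


def lrt_f(fit_full: FitResult, fit_reduced: FitResult, df: pd.DataFrame) -> dict:
    """Extra-sum-of-squares F comparison on weighted residuals.

    F = ((WRSS_reduced - WRSS_full) / df1) / (WRSS_full / df2) with
    df1 = difference in mean-parameter count and df2 = n - k_full (k_full
    counts sigma2).  WRSS_full = 0 yields F = inf.
    """
    n = fit_full.n_obs
    if fit_reduced.n_obs != n:
        raise ValueError("both fits must be on identical data")
    df1 = (fit_full.n_params - 1) - (fit_reduced.n_params - 1)
    if df1 <= 0:
        raise ValueError("full model must have more parameters than reduced")
    df2 = n - fit_full.n_params
    w_full = fit_full.weighted_rss
    w_red = fit_reduced.weighted_rss
    if w_full == 0.0:
        return {"F": math.inf, "df1": df1, "df2": df2, "p": 0.0}
    F = ((w_red - w_full) / df1) / (w_full / df2)
    p = float(stats.f.sf(F, df1, df2)) if F >= 0 else 1.0
    return {"F": float(F), "df1": int(df1), "df2": int(df2), "p": p}


def lrt_chi2(fit_full: FitResult, fit_reduced: FitResult) -> dict:
    """Chi-square likelihood-ratio variant (2 delta lnL on df1 degrees)."""
    df1 = fit_full.n_params - fit_reduced.n_params
    if df1 <= 0:
        df1 = 1
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    return {
        "chi2": float(stat),
        "df": int(df1),
        "p": float(stats.chi2.sf(max(stat, 0.0), df1)),
    }


def compare_families(
    df: pd.DataFrame, n_starts: int = 20, seed: int = 0
) -> dict:
    """Fit both families to the same table and report AIC plus the F comparison."""
    fg = fit(df, "generalized", n_starts=n_starts, seed=seed)
    fc = fit(df, "conventional", n_starts=n_starts, seed=seed)
    comparison = lrt_f(fg, fc, df)
    return {
        "generalized": fg,
        "conventional": fc,
        "aic_general": fg.aic,
        "aic_conventional": fc.aic,
        "delta_aic": fc.aic - fg.aic,
        **comparison,
    }


def predict_per_female(
    params: FecundityModelParams,
    n_pairs: np.ndarray | float,
    n_het_males: np.ndarray | float,
    date_day: float = DEFAULT_PREDICTION_DAY,
) -> np.ndarray:
    """Predicted eggs per female at given densities (default: median date 230)."""
    tbl = pd.DataFrame(
        {
            "date_day": np.broadcast_arrays(
                np.asarray(n_pairs, float), np.asarray(n_het_males, float)
            )[0] * 0.0 + date_day,
            "n_pairs": np.asarray(n_pairs, float),
            "n_het_males": np.asarray(n_het_males, float),
        }
    )
    return mean_fecundity(tbl, params) / tbl["n_pairs"].to_numpy(float)
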