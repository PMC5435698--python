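"""Phase-plane analysis: isoclines, invasion thresholds, equilibria, regimes.

The zero-growth isocline of species *i* is the curve in the (N1, N2) plane
where its per-capita growth vanishes.  For the generalized (encounter-rate)
model the isocline has the closed form, writing u = b_ij (1-s_i) N_i,
L = ln[(1-s_i) B_i0 / (D_i + H_i N_i)]:

    b_jj (1-s_j) N_j = L b_jj (1-s_j) (S + u) / (a_ij s_j - b_jj (1-s_j) L)

which does not pass through the origin unless L(0) = 0 — at low total density
interference is weak and growth is positive.  The conventional isocline

    i_ij s_j N_j = s_i N_i [ (1-s_i) B_i0 / (D_i + H_i N_i) - 1 ]

always passes through the origin: frequency-dependent interference does not
relent at low density.

Whether a rare invader can always establish (its isocline never reaches the
N_j axis) is decided by a_ij s_j <= b_jj (1-s_j) ln[(1-s_i) B_i0 / D_i];
otherwise the isocline meets the axis at a finite resident density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import growth_rate
from .params import CommunitySpec, ConventionalRIParams, GeneralizedRIParams

__all__ = [
    "IsoclineCurve",
    "Equilibrium",
    "InvasionResult",
    "RegimeReport",
    "isocline",
    "isocline_generalized",
    "isocline_conventional",
    "invasion_threshold",
    "find_equilibria",
    "classify_stability",
    "classify_regime",
    "per_capita_growth",
]

logger = logging.getLogger(__name__)

#: absolute tolerance on per-capita growth at points declared to be on an
#: isocline or at an equilibrium — far below any biological resolution
GROWTH_TOL = 1e-8


def per_capita_growth(spec: CommunitySpec, N1: float, N2: float, focal: int) -> float:
    """Per-capita growth rate of the focal species (the bracket term).

    Evaluated as growth/N for N > 0; at N = 0 as the limit from the formula
    (finite for the generalized model; for the conventional model the limit
    is direction-dependent and the along-axis value is used).
    """
    N_focal = (N1, N2)[focal]
    if N_focal > 0:
        return growth_rate(spec, N1, N2, focal) / N_focal
    h = 1e-12
    pt = (h, N2) if focal == 0 else (N1, h)
    return growth_rate(spec, pt[0], pt[1], focal) / h


@dataclass(frozen=True)
class IsoclineCurve:
    """Zero-growth isocline of one species.

    ``points`` is an (n, 2) array of (N_focal, N_other) pairs restricted to
    the domain where the closed form is defined and N_other >= 0; undefined
    or negative branches are dropped, not extrapolated.  ``kind`` is
    "explicit" for the closed-form branch or "vertical" for the
    interference-free line N_focal = K.
    """

    focal: int
    points: np.ndarray
    kind: str = "explicit"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts)

    @property
    def phase_points(self) -> np.ndarray:
        """Points in (N1, N2) phase-plane coordinates."""
        if self.focal == 0:
            return self.points.copy()
        return self.points[:, ::-1].copy()


@dataclass(frozen=True)
class Equilibrium:
    """A rest point of the two-species dynamics with its local stability."""

    N1: float
    N2: float
    jacobian: np.ndarray
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | unstable | saddle | marginal

    @property
    def location(self) -> tuple[float, float]:
        return (self.N1, self.N2)

    @property
    def is_boundary(self) -> bool:
        return self.N1 <= 0.0 or self.N2 <= 0.0

    @property
    def is_interior(self) -> bool:
        return not self.is_boundary


@dataclass(frozen=True)
class InvasionResult:
    """Whether a rare focal species can establish against any resident density."""

    focal: int
    status: str  # always_invades | threshold | nonviable
    N_j_intercept: float | None = None

    @property
    def always_invades(self) -> bool:
        return self.status == "always_invades"


def _vertical_isocline(spec: CommunitySpec, focal: int, grid: np.ndarray) -> IsoclineCurve:
    sp = spec.species[focal]
    K = sp.carrying_capacity
    if not math.isfinite(K) or K <= 0:
        return IsoclineCurve(focal=focal, points=np.empty((0, 2)), kind="vertical")
    pts = np.column_stack([np.full_like(grid, K, dtype=float), np.asarray(grid, float)])
    return IsoclineCurve(focal=focal, points=pts, kind="vertical")


def isocline_generalized(
    spec: CommunitySpec, focal: int, N_i_grid: np.ndarray
) -> IsoclineCurve:
    """Closed-form isocline of the generalized model over a grid of own density.

    Points where the log argument is non-positive, the denominator vanishes
    or N_j < 0 are dropped.  With a_ij = 0 the isocline is the vertical line
    at the carrying capacity; with b_jj (1-s_j) = 0 the N_j solving the
    zero-growth condition is still explicit and that branch is used.
    """
    if spec.family != "generalized":
        raise ValueError("generalized-family spec required")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    inter: GeneralizedRIParams = spec.interaction(focal)
    grid = np.asarray(N_i_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("N_i grid must be >= 0")

    if inter.a == 0.0:
        return _vertical_isocline(spec, focal, grid)

    S = spec.S
    a_s = inter.a * other.s
    bq = inter.b_jj * (1.0 - other.s)  # dilution by heterospecific females

    mort = sp.D + sp.H * grid
    valid = mort > 0
    L = np.full_like(grid, np.nan)
    L[valid] = np.log((1.0 - sp.s) * sp.B0 / mort[valid])
    u = inter.b_ij * (1.0 - sp.s) * grid

    if a_s == 0.0:  # interfering males absent (s_j = 0): vertical line
        return _vertical_isocline(spec, focal, grid)

    if bq == 0.0:
        # exponent reduces to a s_j N_j / (S + u): explicit in N_j
        N_j = L * (S + u) / a_s
    else:
        denom = a_s - bq * L
        with np.errstate(divide="ignore", invalid="ignore"):
            N_j = L * (S + u) / denom
        N_j[denom <= 0] = np.nan

    keep = valid & np.isfinite(N_j) & (N_j >= 0) & (L >= 0)
    pts = np.column_stack([grid[keep], N_j[keep]])
    return IsoclineCurve(focal=focal, points=pts, kind="explicit")


def isocline_conventional(
    spec: CommunitySpec, focal: int, N_i_grid: np.ndarray
) -> IsoclineCurve:
    """Closed-form isocline of the conventional model; passes through the origin."""
    if spec.family != "conventional":
        raise ValueError("conventional-family spec required")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    inter: ConventionalRIParams = spec.interaction(focal)
    grid = np.asarray(N_i_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("N_i grid must be >= 0")

    if inter.i == 0.0 or other.s == 0.0:
        return _vertical_isocline(spec, focal, grid)

    mort = sp.D + sp.H * grid
    with np.errstate(divide="ignore", invalid="ignore"):
        N_j = sp.s * grid * ((1.0 - sp.s) * sp.B0 / mort - 1.0) / (inter.i * other.s)
    N_j = np.where((grid == 0.0), 0.0, N_j)
    keep = np.isfinite(N_j) & (N_j >= 0)
    pts = np.column_stack([grid[keep], N_j[keep]])
    return IsoclineCurve(focal=focal, points=pts, kind="explicit")


def isocline(spec: CommunitySpec, focal: int, N_i_grid: np.ndarray) -> IsoclineCurve:
    """Zero-growth isocline, dispatching on the model family."""
    if spec.family == "generalized":
        return isocline_generalized(spec, focal, N_i_grid)
    return isocline_conventional(spec, focal, N_i_grid)


def invasion_threshold(spec: CommunitySpec, focal: int) -> InvasionResult:
    """Can a rare focal species establish regardless of resident abundance?

    Generalized family only.  The focal species always invades when
    a_ij s_j <= b_jj (1-s_j) ln[(1-s_i) B_i0 / D_i]; otherwise its isocline
    meets the N_j axis at

        N_j* = [S / (b_jj (1-s_j))] *
               [a_ij s_j / (a_ij s_j - b_jj (1-s_j) L0) - 1],   L0 = ln[(1-s_i) B_i0 / D_i]

    above which the rare invader declines.  A species whose low-density
    growth is non-positive even alone is reported as nonviable.
    """
    if spec.family != "generalized":
        raise ValueError("invasion_threshold applies to the generalized family")
    sp = spec.species[focal]
    other = spec.species[1 - focal]
    inter: GeneralizedRIParams = spec.interaction(focal)

    if sp.low_density_growth <= 0:
        return InvasionResult(focal=focal, status="nonviable")
    a_s = inter.a * other.s
    if a_s == 0.0:
        return InvasionResult(focal=focal, status="always_invades")
    if sp.D == 0.0:
        # no background mortality: any positive residual birth rate suffices
        bq = inter.b_jj * (1.0 - other.s)
        if bq > 0.0:
            return InvasionResult(focal=focal, status="always_invades")
        return InvasionResult(focal=focal, status="threshold", N_j_intercept=math.inf)

    L0 = math.log((1.0 - sp.s) * sp.B0 / sp.D)
    bq = inter.b_jj * (1.0 - other.s)
    if bq == 0.0:
        # exponent grows without bound in N_j; intercept from a s_j N_j / S = L0
        return InvasionResult(
            focal=focal, status="threshold", N_j_intercept=spec.S * L0 / a_s
        )
    if a_s <= bq * L0:
        return InvasionResult(focal=focal, status="always_invades")
    intercept = (spec.S / bq) * (a_s / (a_s - bq * L0) - 1.0)
    return InvasionResult(focal=focal, status="threshold", N_j_intercept=intercept)


# ---------------------------------------------------------------------------
# equilibria


def _default_search_box(spec: CommunitySpec) -> tuple[float, float]:
    Ks = [sp.carrying_capacity for sp in spec.species]
    finite = [K for K in Ks if math.isfinite(K) and K > 0]
    if not finite:
        raise ValueError(
            "cannot infer a search box (no finite carrying capacity); pass search_box"
        )
    K = max(finite)
    return (2.0 * K, 2.0 * K)


def _jacobian(spec: CommunitySpec, N1: float, N2: float) -> np.ndarray:
    """Numeric Jacobian of the growth field; one-sided at the axes."""
    J = np.empty((2, 2))
    N = np.array([N1, N2], dtype=float)
    for k in range(2):
        h = 1e-6 * (1.0 + abs(N[k]))
        if N[k] - h < 0:  # stay in the non-negative quadrant
            lo, hi = N[k], N[k] + h
        else:
            lo, hi = N[k] - h, N[k] + h
        p_lo, p_hi = N.copy(), N.copy()
        p_lo[k], p_hi[k] = lo, hi
        for i in range(2):
            g_hi = growth_rate(spec, p_hi[0], p_hi[1], i)
            g_lo = growth_rate(spec, p_lo[0], p_lo[1], i)
            J[i, k] = (g_hi - g_lo) / (hi - lo)
    return J


def classify_stability(
    spec: CommunitySpec, location: tuple[float, float], tol: float = 1e-7
) -> Equilibrium:
    """Linearize at a rest point and label it by its eigenvalue real parts.

    stable: both real parts < -tol; unstable: both > tol; saddle: opposite
    signs; marginal: any real part within tol of zero.  The Jacobian is built
    by central finite differences (one-sided on the axes, where the dynamics
    are only defined for non-negative densities).
    """
    N1, N2 = float(location[0]), float(location[1])
    J = _jacobian(spec, N1, N2)
    eig = np.linalg.eigvals(J)
    re = np.sort(eig.real)
    if re[1] < -tol:
        label = "stable"
    elif re[0] > tol:
        label = "unstable"
    elif re[0] < -tol and re[1] > tol:
        label = "saddle"
    else:
        label = "marginal"
    return Equilibrium(
        N1=N1, N2=N2, jacobian=J, eigenvalues=(complex(eig[0]), complex(eig[1])),
        stability=label,
    )


def find_equilibria(
    spec: CommunitySpec,
    search_box: tuple[float, float] | None = None,
    grid_density: int = 200,
    growth_tol: float = 1e-6,
) -> list[Equilibrium]:
    """Locate all rest points of the two-species dynamics inside a box.

    Interior candidates are cells of a regular grid where both per-capita
    growth fields change sign; each is refined by 2-D root iteration on the
    per-capita rates.  Boundary equilibria — the origin and the
    single-species carrying capacities — are always included when they
    exist.  Every returned point re-evaluates to |growth| < ``growth_tol``.
    """
    if search_box is None:
        box = _default_search_box(spec)
    else:
        box = (float(search_box[0]), float(search_box[1]))
    if min(box) <= 0:
        raise ValueError("search box must have positive extent")

    eqs: list[tuple[float, float]] = [(0.0, 0.0)]
    for focal in (0, 1):
        K = spec.species[focal].carrying_capacity
        if math.isfinite(K) and K > 0:
            eqs.append((K, 0.0) if focal == 0 else (0.0, K))

    # interior scan on per-capita brackets (strictly positive grid)
    n = grid_density
    g1 = np.linspace(box[0] / n, box[0], n)
    g2 = np.linspace(box[1] / n, box[1], n)
    P1 = np.empty((n, n))
    P2 = np.empty((n, n))
    for i, x in enumerate(g1):
        for j, y in enumerate(g2):
            P1[i, j] = per_capita_growth(spec, x, y, 0)
            P2[i, j] = per_capita_growth(spec, x, y, 1)

    sign_change = lambda A: (
        (np.sign(A[:-1, :-1]) != np.sign(A[1:, :-1]))
        | (np.sign(A[:-1, :-1]) != np.sign(A[:-1, 1:]))
        | (np.sign(A[:-1, :-1]) != np.sign(A[1:, 1:]))
    )
    cells = np.argwhere(sign_change(P1) & sign_change(P2))

    def brackets(v: np.ndarray) -> np.ndarray:
        return np.array(
            [per_capita_growth(spec, v[0], v[1], 0), per_capita_growth(spec, v[0], v[1], 1)]
        )

    dedupe_r = 1e-4 * max(box)
    for ci, cj in cells:
        x0 = np.array([0.5 * (g1[ci] + g1[ci + 1]), 0.5 * (g2[cj] + g2[cj + 1])])
        sol = optimize.root(brackets, x0, method="hybr", tol=1e-12)
        if not sol.success:
            sol = optimize.root(brackets, x0, method="lm", tol=1e-14)
        if not sol.success:
            logger.warning("equilibrium refinement failed near %s", tuple(x0))
            continue
        x = sol.x
        if np.any(x < dedupe_r * 1e-3) or np.any(x > 2 * max(box)):
            continue  # converged onto a boundary/out-of-box point
        if any(math.hypot(x[0] - e[0], x[1] - e[1]) < dedupe_r for e in eqs):
            continue
        eqs.append((float(x[0]), float(x[1])))

    out: list[Equilibrium] = []
    for N1, N2 in eqs:
        g = (growth_rate(spec, N1, N2, 0), growth_rate(spec, N1, N2, 1))
        scale = max(1.0, N1, N2)
        if max(abs(g[0]), abs(g[1])) > growth_tol * scale:
            logger.warning("dropping non-converged candidate (%g, %g)", N1, N2)
            continue
        out.append(classify_stability(spec, (N1, N2)))
    return out


@dataclass(frozen=True)
class RegimeReport:
    """Qualitative classification of a community's phase-plane structure."""

    n_stable_interior: int
    n_unstable_interior: int
    origin_positive_growth: bool
    species1_always_invades: bool
    species2_always_invades: bool
    priority_effect_present: bool
    bistable_coexistence: bool
    equilibria: tuple[Equilibrium, ...] = field(default=(), repr=False)


def classify_regime(
    spec: CommunitySpec,
    search_box: tuple[float, float] | None = None,
    grid_density: int = 200,
) -> RegimeReport:
    """Count interior equilibria and flag the qualitative dynamical regime.

    ``priority_effect_present``: at least two attractors exist (excluding the
    origin) of which at least one is a single-species exclusion state, so the
    outcome depends on initial abundances.  ``bistable_coexistence``: two or
    more stable interior equilibria.  ``origin_positive_growth``: both species
    grow at vanishing total density — always true for the generalized model
    when (1-s) B0 > D, never for the conventional model with interference.
    """
    eqs = find_equilibria(spec, search_box=search_box, grid_density=grid_density)
    interior = [e for e in eqs if e.is_interior]
    n_stable_int = sum(e.stability == "stable" for e in interior)
    n_unstable_int = len(interior) - n_stable_int

    scale = max(
        [sp.carrying_capacity for sp in spec.species if math.isfinite(sp.carrying_capacity)]
        or [1.0]
    )
    eps = 1e-6 * max(scale, 1.0)
    origin_pos = all(per_capita_growth(spec, eps, eps, f) > 0 for f in (0, 1))

    invades = []
    for focal in (0, 1):
        if spec.family == "generalized":
            invades.append(invasion_threshold(spec, focal).always_invades)
        else:
            K_res = spec.species[1 - focal].carrying_capacity
            if not math.isfinite(K_res) or K_res <= 0:
                invades.append(per_capita_growth(spec, eps, eps, focal) > 0)
            else:
                pt = (eps, K_res) if focal == 0 else (K_res, eps)
                invades.append(per_capita_growth(spec, pt[0], pt[1], focal) > 0)

    attractors = [e for e in eqs if e.stability == "stable" and e.location != (0.0, 0.0)]
    boundary_attractors = [e for e in attractors if e.is_boundary]
    priority = len(attractors) >= 2 and len(boundary_attractors) >= 1

    return RegimeReport(
        n_stable_interior=n_stable_int,
        n_unstable_interior=n_unstable_int,
        origin_positive_growth=origin_pos,
        species1_always_invades=invades[0],
        species2_always_invades=invades[1],
        priority_effect_present=priority,
        bistable_coexistence=n_stable_int >= 2,
        equilibria=tuple(eqs),
    )
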