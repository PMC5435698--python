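"""Time integration and outcome classification for two-species interference dynamics.

Continuous trajectories are produced with an adaptive Runge-Kutta scheme.
Densities below an absorbing extinction threshold are pinned to zero: the
event is detected during integration, the extinct component is frozen and
integration restarts, so the N = 0 axes are exactly invariant.

Discrete-generation trajectories iterate the per-generation maps with a
synchronous update — both species read the generation-t state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    discrete_step_conventional,
    discrete_step_generalized,
    growth_rate,
    two_sex_rates,
)
from .params import CommunitySpec

__all__ = [
    "Trajectory",
    "integrate",
    "iterate_discrete",
    "classify_outcome",
    "OutcomeReport",
]

#: densities below this are treated as extinct (absorbing)
EXTINCTION_THRESHOLD = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: strictly increasing times and non-negative states."""

    times: np.ndarray
    states: np.ndarray  # (n, 2) totals or (n, 4) sex-resolved (F1, M1, F2, M2)
    model_family: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("states must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    @property
    def totals(self) -> np.ndarray:
        """(n, 2) array of total densities, summing sexes if resolved."""
        if self.states.shape[1] == 2:
            return self.states
        return np.column_stack(
            [self.states[:, 0] + self.states[:, 1], self.states[:, 2] + self.states[:, 3]]
        )

    @property
    def final(self) -> np.ndarray:
        return self.totals[-1]


def integrate(
    spec: CommunitySpec,
    initial: Sequence[float],
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    two_sex: bool = False,
    n_points: int = 200,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the continuous dynamics from ``initial`` up to ``t_end``.

    ``initial`` is (N1, N2) for the total-density form or (F1, M1, F2, M2)
    with ``two_sex=True``.  Extinctions are absorbing: when a species' total
    crosses ``extinction_threshold`` from above it is set to exactly zero
    for the rest of the run, and the event is recorded in ``meta``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = np.asarray(initial, dtype=float)
    dim = 4 if two_sex else 2
    if y0.shape != (dim,):
        raise ValueError(f"initial state must have {dim} components")
    if np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite and non-negative")

    alive = [y0[:2].copy() if not two_sex else None]  # placeholder, see totals fn

    def totals(y: np.ndarray) -> np.ndarray:
        if two_sex:
            return np.array([y[0] + y[1], y[2] + y[3]])
        return y

    extinct = totals(y0) <= extinction_threshold
    if two_sex:
        for k in np.flatnonzero(extinct):
            y0[2 * k : 2 * k + 2] = 0.0
    else:
        y0[extinct] = 0.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.maximum(y, 0.0)
        if two_sex:
            F1, M1, F2, M2 = y
            if extinct[0]:
                F1 = M1 = 0.0
            if extinct[1]:
                F2 = M2 = 0.0
            d1 = two_sex_rates(spec, F1, M1, F2, M2, 0) if not extinct[0] else (0.0, 0.0)
            d2 = two_sex_rates(spec, F1, M1, F2, M2, 1) if not extinct[1] else (0.0, 0.0)
            return np.array([d1[0], d1[1], d2[0], d2[1]])
        N1 = 0.0 if extinct[0] else y[0]
        N2 = 0.0 if extinct[1] else y[1]
        return np.array(
            [
                0.0 if extinct[0] else growth_rate(spec, N1, N2, 0),
                0.0 if extinct[1] else growth_rate(spec, N1, N2, 1),
            ]
        )

    def extinction_event(k: int):
        def ev(t: float, y: np.ndarray) -> float:
            if extinct[k]:
                return 1.0
            return totals(np.maximum(y, 0.0))[k] - extinction_threshold

        ev.terminal = True
        ev.direction = -1.0
        return ev

    t0 = 0.0
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    events: list[dict] = []
    y = y0.copy()
    while True:
        t_eval = np.linspace(t0, t_end, max(2, int(n_points * (t_end - t0) / t_end) + 1))
        sol = solve_ivp(
            rhs,
            (t0, t_end),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
            events=[extinction_event(0), extinction_event(1)],
        )
        if sol.status == -1:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else t0}: {sol.message}; "
                f"last state {sol.y[:, -1] if sol.y.size else y}"
            )
        ts.append(sol.t)
        ys.append(np.maximum(sol.y.T, 0.0))
        if sol.status == 0:  # reached t_end
            break
        # an extinction event fired: pin the species at 0 and continue
        t_ev = min(te[0] for te in sol.t_events if len(te))
        y = np.maximum(sol.sol(t_ev) if sol.sol is not None else sol.y[:, -1], 0.0)
        for k in (0, 1):
            if not extinct[k] and len(sol.t_events[k]) and sol.t_events[k][0] <= t_ev + 1e-12:
                extinct[k] = True
                events.append({"species": k + 1, "time": float(t_ev)})
                if two_sex:
                    y[2 * k : 2 * k + 2] = 0.0
                else:
                    y[k] = 0.0
        t0 = t_ev
        if t0 >= t_end:
            break

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    traj = Trajectory(
        times=t_all[keep],
        states=y_all[keep],
        model_family=spec.family,
        meta={
            "solver": method,
            "rtol": rtol,
            "atol": atol,
            "extinction_threshold": extinction_threshold,
            "extinctions": events,
            "two_sex": two_sex,
        },
    )
    return traj


def iterate_discrete(
    R: Sequence[float],
    interference: Sequence,
    H: Sequence[float],
    initial: Sequence[float],
    n_generations: int,
    family: str = "generalized",
    S: float = 1.0,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> Trajectory:
    """Iterate the discrete-generation maps for both species synchronously.

    ``R``, ``H`` are per-species; ``interference`` holds the directed blocks
    (effect on species 1, effect on species 2) — GeneralizedRIParams (only
    ``a`` and ``b_ij`` enter the fitted map) or ConventionalRIParams.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    N = np.asarray(initial, dtype=float)
    if N.shape != (2,) or np.any(N < 0):
        raise ValueError("initial must be a non-negative pair")
    out = np.empty((n_generations + 1, 2))
    out[0] = N
    for t in range(n_generations):
        cur = out[t]
        nxt = np.empty(2)
        for k in (0, 1):
            Nk, Nj = cur[k], cur[1 - k]
            if family == "generalized":
                blk = interference[k]
                nxt[k] = discrete_step_generalized(R[k], blk.a, blk.b_ij, H[k], S, Nk, Nj)
            else:
                nxt[k] = discrete_step_conventional(R[k], interference[k].i, H[k], Nk, Nj)
            if nxt[k] <= extinction_threshold:
                nxt[k] = 0.0
        out[t + 1] = nxt
    return Trajectory(
        times=np.arange(n_generations + 1, dtype=float),
        states=out,
        model_family=family,
        meta={"discrete": True, "S": S, "extinction_threshold": extinction_threshold},
    )


@dataclass(frozen=True)
class OutcomeReport:
    """Per-initial-condition outcome labels plus the global verdict."""

    labels: tuple[str, ...]
    global_label: str
    finals: tuple[tuple[float, float], ...]


def _label_trajectory(
    spec: CommunitySpec,
    traj: Trajectory,
    extinction_threshold: float,
    settle_tol: float,
) -> str:
    N1, N2 = traj.final
    alive1 = N1 > extinction_threshold
    alive2 = N2 > extinction_threshold
    if alive1 and not alive2:
        return "exclusion_of_2"
    if alive2 and not alive1:
        return "exclusion_of_1"
    if not alive1 and not alive2:
        return "undecided"  # joint collapse is outside the model's taxonomy
    # both alive: coexistence only if the state has settled
    scale = max(N1, N2, 1.0)
    g = (abs(growth_rate(spec, N1, N2, 0)), abs(growth_rate(spec, N1, N2, 1)))
    if max(g) < settle_tol * scale:
        return "coexistence"
    return "undecided"


def classify_outcome(
    spec: CommunitySpec,
    initial_conditions: Sequence[Sequence[float]],
    horizon: float,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    settle_tol: float = 1e-6,
    rtol: float = 1e-8,
) -> OutcomeReport:
    """Integrate from each initial condition and label the long-run outcome.

    Per-trajectory labels: coexistence (both persist at a settled state),
    exclusion_of_1 / exclusion_of_2, or undecided when neither threshold is
    crossed within the horizon.  The global label is ``priority_effect``
    when different initial conditions lead to different exclusion outcomes,
    otherwise the common label (or ``mixed``).
    """
    if not len(initial_conditions):
        raise ValueError("at least one initial condition required")
    labels: list[str] = []
    finals: list[tuple[float, float]] = []
    for init in initial_conditions:
        traj = integrate(
            spec, init, horizon, rtol=rtol, extinction_threshold=extinction_threshold
        )
        labels.append(_label_trajectory(spec, traj, extinction_threshold, settle_tol))
        finals.append((float(traj.final[0]), float(traj.final[1])))
    exclusions = {l for l in labels if l.startswith("exclusion")}
    if len(exclusions) > 1:
        global_label = "priority_effect"
    elif len(set(labels)) == 1:
        global_label = labels[0]
    else:
        global_label = "mixed"
    return OutcomeReport(labels=tuple(labels), global_label=global_label, finals=tuple(finals))
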