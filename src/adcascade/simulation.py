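"""Integration of the biomarker cascade ODEs over the age span.

The system is small and non-stiff, so an adaptive explicit Runge-Kutta
scheme (``scipy.integrate.solve_ivp``, RK45) with tight tolerances is used.
Two details need care:

* the anti-amyloid therapy input is a step function, so the age span is
  split at the therapy onset and each piece integrated with a constant
  therapy level — the adaptive stepper never sees the discontinuity;
* the literal state-independent clearance term can drive the amyloid level
  below zero, which is unphysical; a nonnegativity floor holds depleted
  states at 0 (their derivative is projected to 0 while non-positive and
  falling), output levels are clamped at 0, and integration restarts from
  the clamped state if a level still falls below ``-1e-9``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from adcascade.model_core import rhs_array, therapy_input

if TYPE_CHECKING:  # pragma: no cover
    from adcascade.scenarios import ScenarioConfig

__all__ = [
    "AgeGrid",
    "Trajectory",
    "SolverFailure",
    "simulate",
    "simulate_risk_pair",
    "export_risk_pair_csv",
    "load_risk_pair_csv",
]

#: Integrator tolerances; far below any detection or acceptance threshold.
RTOL = 1e-8
ATOL = 1e-10

#: Integrated states more negative than this trigger a clamp-and-restart.
NEGATIVE_TOL = -1e-9

_STATE_COLUMNS = ("a_beta", "tau_p", "tau_o", "n_deg", "cog")


class SolverFailure(RuntimeError):
    """Raised when the ODE integrator cannot meet its tolerances."""


@dataclass(frozen=True)
class AgeGrid:
    """Output grid: ages from ``start`` to ``end`` spaced by ``step`` years."""

    start: float = 0.0
    end: float = 100.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"AgeGrid start ({self.start}) must be < end ({self.end})")
        if not self.step > 0:
            raise ValueError(f"AgeGrid step must be > 0, got {self.step}")

    def points(self) -> np.ndarray:
        n = int(np.floor((self.end - self.start) / self.step + 1e-9))
        pts = self.start + self.step * np.arange(n + 1)
        if pts[-1] < self.end - 1e-9:
            pts = np.append(pts, self.end)
        else:
            pts[-1] = self.end
        return pts


@dataclass
class Trajectory:
    """Dense solution of one scenario: per-age levels of all biomarkers.

    ``cog`` is the cognition curve for the reserve value recorded in
    ``reserve``; total tau is derived on demand as ``tau_p + tau_o``.
    """

    ages: np.ndarray
    a_beta: np.ndarray
    tau_p: np.ndarray
    tau_o: np.ndarray
    n_deg: np.ndarray
    cog: np.ndarray
    reserve: float = 1.0
    config_ref: "ScenarioConfig | None" = field(default=None, repr=False)

    @property
    def tau_total(self) -> np.ndarray:
        return self.tau_p + self.tau_o

    def series(self, name: str) -> np.ndarray:
        """Level array for a biomarker name, including derived ``tau_total``."""
        if name == "tau_total":
            return self.tau_total
        if name in _STATE_COLUMNS:
            return getattr(self, name)
        raise KeyError(f"unknown biomarker {name!r}")

    def at_age(self, age: float, name: str) -> float:
        """Linearly interpolated level of one biomarker at an arbitrary age."""
        return float(np.interp(age, self.ages, self.series(name)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "a_beta": self.a_beta,
                "tau_p": self.tau_p,
                "tau_o": self.tau_o,
                "tau_total": self.tau_total,
                "n_deg": self.n_deg,
                "cog": self.cog,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        missing = {"age", "a_beta", "tau_p", "tau_o", "n_deg", "cog"} - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        return cls(
            ages=df["age"].to_numpy(float),
            a_beta=df["a_beta"].to_numpy(float),
            tau_p=df["tau_p"].to_numpy(float),
            tau_o=df["tau_o"].to_numpy(float),
            n_deg=df["n_deg"].to_numpy(float),
            cog=df["cog"].to_numpy(float),
        )


def _integrate_segment(fun, t0, t1, y0, grid_ages, out_rows, rtol, atol):
    """Integrate [t0, t1], writing grid points into out_rows; clamp-restart on
    negative excursions. Returns the (clamped) state at t1."""
    t_cur = t0
    y = np.asarray(y0, float)
    while True:
        y = np.maximum(y, 0.0)
        if t_cur >= t1:
            return y
        sol = solve_ivp(
            fun, (t_cur, t1), y, method="RK45", rtol=rtol, atol=atol, dense_output=True
        )
        if not sol.success:
            raise SolverFailure(f"integration failed on [{t_cur}, {t1}]: {sol.message}")
        mask = (grid_ages > t_cur + 1e-12) & (grid_ages <= t1 + 1e-12)
        idx = np.nonzero(mask)[0]
        if idx.size:
            Y = sol.sol(grid_ages[idx]).T  # (n_points, 5)
            bad = np.nonzero(Y.min(axis=1) < NEGATIVE_TOL)[0]
            if bad.size:
                j = bad[0]
                out_rows[idx[: j + 1]] = Y[: j + 1]
                out_rows[idx[j]] = np.maximum(Y[j], 0.0)
                t_cur = grid_ages[idx[j]]
                y = out_rows[idx[j]].copy()
                continue
            out_rows[idx] = Y
        y = sol.sol(t1)
        t_cur = t1


def simulate(
    config: "ScenarioConfig",
    grid: AgeGrid | None = None,
    *,
    reserve: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Solve the cascade ODEs for one scenario on an age grid.

    If therapy is active the span is split at the onset age so the step
    input is exact.  All output levels are floored at 0.  Deterministic for
    a given config and grid.

    Parameters
    ----------
    config
        Scenario (initial state, rates, capacities, host factors, therapy).
    grid
        Output ages; defaults to the config's own grid.
    reserve
        Cognitive reserve R for the cognition equation; defaults to the
        low-risk value in ``config.host``.
    """
    from adcascade.scenarios import validate

    violations = validate(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(str(v) for v in violations))

    grid = grid if grid is not None else config.grid
    ages = grid.points()
    r = config.host.reserve_low if reserve is None else reserve
    rates, caps, host = config.rates, config.caps, config.host
    form = config.degradation_form
    sched = config.therapy

    # Segment boundaries: split at therapy onset when it falls inside the span.
    bounds = [grid.start, grid.end]
    if sched.active and grid.start < sched.onset_age < grid.end:
        bounds = [grid.start, sched.onset_age, grid.end]

    out = np.empty((len(ages), 5))
    out[0] = np.maximum(config.initial.as_array(), 0.0)
    y = out[0].copy()
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        # therapy level is constant strictly inside the segment
        a_rx = therapy_input(0.5 * (t0 + t1), sched)

        def fun(t, yv, _a_rx=a_rx):
            dy = rhs_array(yv, rates, caps, host, _a_rx, r, form)
            # nonnegativity floor: a depleted state cannot be driven further
            # down by a state-independent sink
            return np.where((yv <= 0.0) & (dy < 0.0), 0.0, dy)

        y = _integrate_segment(fun, t0, t1, y, ages, out, rtol, atol)

    out = np.maximum(out, 0.0)
    return Trajectory(
        ages=ages,
        a_beta=out[:, 0],
        tau_p=out[:, 1],
        tau_o=out[:, 2],
        n_deg=out[:, 3],
        cog=out[:, 4],
        reserve=r,
        config_ref=config,
    )


def simulate_risk_pair(
    config: "ScenarioConfig", grid: AgeGrid | None = None
) -> tuple[Trajectory, Trajectory]:
    """Simulate the low-risk (R1) and high-risk (R2) cognitive-reserve groups.

    Cognition feeds back into no other equation, so the two trajectories
    share identical amyloid, tau, and neurodegeneration curves and differ
    only in the cognition column.
    """
    low = simulate(config, grid, reserve=config.host.reserve_low)
    high = simulate(config, grid, reserve=config.host.reserve_high)
    return low, high


def export_risk_pair_csv(low: Trajectory, high: Trajectory, path) -> None:
    """Write both risk groups to one CSV (``cog_low``/``cog_high`` columns)."""
    if not np.array_equal(low.ages, high.ages):
        raise ValueError("risk-pair trajectories must share the age grid")
    df = low.to_frame().drop(columns="cog")
    df["cog_low"] = low.cog
    df["cog_high"] = high.cog
    df.to_csv(path, index=False)


def load_risk_pair_csv(path) -> tuple[Trajectory, Trajectory]:
    """Read a risk-pair CSV back into (low, high) trajectories."""
    df = pd.read_csv(path)
    missing = {"age", "a_beta", "tau_p", "tau_o", "cog_low", "cog_high", "n_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"risk-pair CSV missing columns: {sorted(missing)}")
    base = dict(
        ages=df["age"].to_numpy(float),
        a_beta=df["a_beta"].to_numpy(float),
        tau_p=df["tau_p"].to_numpy(float),
        tau_o=df["tau_o"].to_numpy(float),
        n_deg=df["n_deg"].to_numpy(float),
    )
    low = Trajectory(cog=df["cog_low"].to_numpy(float), **base)
    high = Trajectory(cog=df["cog_high"].to_numpy(float), **base)
    return low, high
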