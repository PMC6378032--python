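"""Least-squares calibration of the logistic carrying capacities.

The cascade model is calibrated so every capacity-bearing biomarker —
amyloid, total tau, neurodegeneration, and (high-risk) cognition — reaches
the maximal normalized level of 1 at age 100.  This shapes all curves into
sigmoids that saturate at the end of the modeled lifespan, with
later-starting cascades rising more steeply.  SNAP-tau grows linearly and
carries no capacity of its own; it is calibrated implicitly through total
tau.

Therapy scenarios are calibrated under the no-therapy condition (clearance
rate set to zero) and the fitted capacities then frozen, so the pre-therapy
natural history is unaffected by the later intervention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from adcascade.model_core import CarryingCapacities, TherapySchedule
from adcascade.simulation import AgeGrid, simulate

__all__ = ["CalibrationResult", "calibrate_capacities"]

CAP_BOUNDS = (0.1, 10.0)

#: Biomarkers entering the calibration objective (cognition = high-risk curve).
CALIBRATION_TARGETS = ("a_beta", "tau_total", "n_deg", "cog")


@dataclass(frozen=True)
class CalibrationResult:
    fitted_caps: CarryingCapacities
    residual_ss: float
    converged: bool
    n_evals: int

    def apply(self, config):
        """Return a copy of ``config`` carrying the fitted capacities."""
        return dataclasses.replace(config, caps=self.fitted_caps)

    def report_text(self) -> str:
        lines = [
            f"k_ab = {self.fitted_caps.k_ab:.6f}",
            f"k_tp = {self.fitted_caps.k_tp:.6f}",
            f"k_n = {self.fitted_caps.k_n:.6f}",
            f"k_c = {self.fitted_caps.k_c:.6f}",
            f"residual_ss = {self.residual_ss:.3e}",
            f"converged = {self.converged}",
            f"n_evals = {self.n_evals}",
        ]
        return "\n".join(lines)


def calibrate_capacities(
    config,
    target_age: float = 100.0,
    target_level: float = 1.0,
) -> CalibrationResult:
    """Fit (k_ab, k_tp, k_n, k_c) so the targeted biomarkers hit the target.

    Minimizes the sum of squared deviations of amyloid, total tau,
    neurodegeneration, and high-risk cognition at ``target_age`` from
    ``target_level``, by bounded trust-region least squares started from the
    config's current capacities.  Deterministic given config and start.

    Raises
    ------
    ValueError
        If the target age lies outside the config's grid, the target level
        is not positive, or all four logistic growth rates are zero (no
        capacity then influences the dynamics).
    """
    if not target_level > 0:
        raise ValueError(f"target_level must be > 0, got {target_level}")
    grid = config.grid
    if not (grid.start < target_age <= grid.end):
        raise ValueError(
            f"target_age {target_age} outside the config grid ({grid.start}, {grid.end}]"
        )
    r = config.rates
    if r.lam_ab == r.lam_tp == r.lam_n == r.lam_c == 0:
        raise ValueError("all logistic growth rates are zero; capacities are unidentifiable")

    # Natural-history condition: no therapy, no clearance.
    nat = dataclasses.replace(
        config,
        rates=dataclasses.replace(r, delta_ab=0.0),
        therapy=TherapySchedule(active=False),
    )
    # Coarser output grid for the objective: accuracy comes from the
    # integrator tolerances, not the output spacing.
    cal_grid = AgeGrid(grid.start, target_age, (target_age - grid.start) / 200.0)

    def residuals(k: np.ndarray) -> np.ndarray:
        trial = dataclasses.replace(nat, caps=CarryingCapacities(*k))
        traj = simulate(trial, cal_grid, reserve=config.host.reserve_high)
        return np.array(
            [traj.series(b)[-1] - target_level for b in CALIBRATION_TARGETS]
        )

    x0 = np.clip(config.caps.as_array(), *CAP_BOUNDS)
    res = least_squares(residuals, x0, bounds=CAP_BOUNDS, method="trf")
    return CalibrationResult(
        fitted_caps=CarryingCapacities(*res.x),
        residual_ss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
        n_evals=int(res.nfev),
    )
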