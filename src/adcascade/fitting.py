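"""Synthetic longitudinal observations and parameter recovery.

The cascade model can be run "backward": given noisy longitudinal samples
of one or more biomarker trajectories, recover a small set of free
parameters by bounded nonlinear least squares against the forward model.
The observation generator samples the model's own trajectories on a fixed
age grid and adds independent Gaussian noise truncated at zero (levels are
nonnegative), so recovery studies are fully seeded and reproducible.

Only small parameter subsets are identifiable from single-cascade data;
``{lam_ab, a_beta0}`` from amyloid observations alone is the canonical
example.  Fitting many rates at once is permitted but typically
ill-conditioned.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from adcascade.simulation import AgeGrid, simulate

__all__ = [
    "ObservationSet",
    "FitResult",
    "generate_observations",
    "fit_parameters",
    "FREE_PARAMETERS",
]

# name -> (config section, dataclass field) for every fittable parameter
FREE_PARAMETERS: dict[str, tuple[str, str]] = {
    # initial values
    "a_beta0": ("initial", "a_beta"),
    "tau_p0": ("initial", "tau_p"),
    "tau_o0": ("initial", "tau_o"),
    "n_deg0": ("initial", "n_deg"),
    "cog0": ("initial", "cog"),
    # rate constants
    **{
        name: ("rates", name)
        for name in (
            "lam_ab",
            "lam_ab_ao",
            "delta_ab",
            "lam_tp_ab",
            "lam_tp",
            "lam_to_as",
            "lam_n",
            "lam_n_tp",
            "lam_n_to",
            "lam_n_as",
            "lam_c",
            "lam_cn",
            "lam_c_as",
            "lam_c_eps",
        )
    },
    # carrying capacities
    **{name: ("caps", name) for name in ("k_ab", "k_tp", "k_n", "k_c")},
    # host factors
    "a_o": ("host", "a_o"),
    "as_level": ("host", "as_level"),
    "eps": ("host", "eps"),
}

_DEFAULT_BOUNDS = (0.0, 10.0)


@dataclass
class ObservationSet:
    """Noisy longitudinal samples of model biomarker trajectories."""

    ages: np.ndarray
    values: dict[str, np.ndarray]
    noise_sd: float = 0.0
    seed: int | None = None
    truth_ref: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        if self.ages.size and np.any(np.diff(self.ages) <= 0):
            raise ValueError("observation ages must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_obs(self) -> int:
        return sum(v.size for v in self.values.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": a, "biomarker": b, "value": v}
            for b, vals in self.values.items()
            for a, v in zip(self.ages, vals)
        ]
        return pd.DataFrame(rows, columns=["age", "biomarker", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        df = pd.read_csv(path)
        missing = {"age", "biomarker", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
        wide = df.pivot_table(index="age", columns="biomarker", values="value")
        ages = wide.index.to_numpy(float)
        values = {b: wide[b].to_numpy(float) for b in wide.columns}
        return cls(ages=ages, values=values)


def generate_observations(
    config,
    ages,
    biomarkers: tuple[str, ...] = ("a_beta",),
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    reserve: float | None = None,
) -> ObservationSet:
    """Sample the model at the given ages with additive truncated-Gaussian noise.

    Reproducible: the same seed yields the same observation set.
    """
    ages = np.asarray(ages, float)
    grid = config.grid
    if ages.size == 0:
        raise ValueError("no observation ages given")
    if ages.min() < grid.start or ages.max() > grid.end:
        raise ValueError(
            f"observation ages must lie within the config grid [{grid.start}, {grid.end}]"
        )
    traj = simulate(config, reserve=reserve)
    rng = np.random.default_rng(seed)
    values = {}
    for b in biomarkers:
        clean = np.interp(ages, traj.ages, traj.series(b))
        noisy = clean + rng.normal(0.0, noise_sd, size=ages.size) if noise_sd > 0 else clean
        values[b] = np.maximum(noisy, 0.0)
    return ObservationSet(
        ages=ages, values=values, noise_sd=noise_sd, seed=seed, truth_ref=config
    )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded least-squares parameter recovery."""

    fitted_params: dict[str, float]
    residual_ss: float
    converged: bool
    bounds: dict[str, tuple[float, float]]
    n_evals: int = 0

    def report_text(self) -> str:
        lines = [f"{k} = {v:.6g}" for k, v in self.fitted_params.items()]
        lines += [
            f"residual_ss = {self.residual_ss:.6e}",
            f"converged = {self.converged}",
            f"n_evals = {self.n_evals}",
        ]
        return "\n".join(lines)


def _set_params(config, names: list[str], x: np.ndarray):
    updates: dict[str, dict[str, float]] = {}
    for name, value in zip(names, x):
        section, fld = FREE_PARAMETERS[name]
        updates.setdefault(section, {})[fld] = float(value)
    for section, kv in updates.items():
        sub = dataclasses.replace(getattr(config, section), **kv)
        config = dataclasses.replace(config, **{section: sub})
    return config


def fit_parameters(
    obs: ObservationSet,
    base_config,
    free: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    init: dict[str, float] | None = None,
    *,
    reserve: float | None = None,
) -> FitResult:
    """Recover free parameters by least squares against the forward model.

    Minimizes the sum of squared residuals between the simulated and
    observed levels at the observation ages, over the named free
    parameters.  All other parameters stay at their ``base_config`` values.
    Deterministic given the inputs.

    Parameters
    ----------
    free
        Names from :data:`FREE_PARAMETERS`, e.g. ``["lam_ab", "a_beta0"]``.
    bounds
        Per-parameter (lower, upper); default (0, 10).
    init
        Starting values; default is the base config's current value,
        nudged inside the bounds.
    """
    if obs.n_obs == 0:
        raise ValueError("observation set is empty; nothing to fit")
    unknown = [n for n in free if n not in FREE_PARAMETERS]
    if unknown:
        raise ValueError(f"unknown free parameters: {unknown}")
    bounds = bounds or {}
    init = init or {}
    lo = np.array([bounds.get(n, _DEFAULT_BOUNDS)[0] for n in free])
    hi = np.array([bounds.get(n, _DEFAULT_BOUNDS)[1] for n in free])

    def current_value(name):
        section, fld = FREE_PARAMETERS[name]
        return getattr(getattr(base_config, section), fld)

    x0 = np.array([init.get(n, current_value(n)) for n in free], float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial values must lie within bounds")

    obs_names = list(obs.values)
    obs_vec = np.concatenate([obs.values[b] for b in obs_names])

    def residuals(x: np.ndarray) -> np.ndarray:
        cfg = _set_params(base_config, free, x)
        traj = simulate(cfg, reserve=reserve)
        sim = np.concatenate(
            [np.interp(obs.ages, traj.ages, traj.series(b)) for b in obs_names]
        )
        return sim - obs_vec

    if not free:
        r = residuals(np.array([]))
        return FitResult(
            fitted_params={}, residual_ss=float(np.sum(r**2)), converged=True, bounds={}, n_evals=1
        )

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    return FitResult(
        fitted_params={n: float(v) for n, v in zip(free, res.x)},
        residual_ss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
        bounds={n: (float(l), float(h)) for n, l, h in zip(free, lo, hi)},
        n_evals=int(res.nfev),
    )
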