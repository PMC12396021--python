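"""Six-state ODE model of Beclin-1 mediated autophagy-apoptosis crosstalk.

The model tracks five dimensionless abundances under a piecewise-constant
ischemic stress S(t):

    B   Beclin-1
    Bc  cleaved Beclin-1 (pro-apoptotic fragment)
    A   autophagosomes
    M   damaged mitochondria
    C   active Caspase-3 (confined to [0, 1]; 1 = full apoptotic activation)

with the derived autophagic flux J = beta_A * A / (1 + A / phi_A) (saturable;
supremum beta_A * phi_A).  The dynamics:

    dB/dt  = alpha_B * (1 + u_B * S) - beta_B * C * B - gamma_B * B
    dBc/dt = beta_B * C * B - gamma_BC * Bc
    dA/dt  = alpha_A * B - J
    dM/dt  = alpha_M * (1 + u_M * S) + sigma_M * Bc - gamma_M * J * M
    dC/dt  = (alpha_C*M + sigma_C*A + mu_C*C/(phi_C+1-C)) * (1-C)
             - gamma_C * C / (phi_C + sigma_J*J + C)

The saturable activation and inactivation of Caspase-3 produce zero-order
ultrasensitivity: for the fixed intrinsic parameters (mu_C=1, gamma_C=0.3,
phi_C=0.15) the isolated Caspase subsystem is bistable, with a low-C
survival state and a high-C apoptotic state (see
:mod:`beclin_duality.caspase_switch`).

All rates are per hour; abundances are normalized so that unstressed
resting levels are ~1 (C excepted).  A cell is classified apoptotic when
C exceeds 0.5 at the end of the simulation horizon.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from . import _kernels

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "REPRESENTATIVE_VALUES",
    "ParameterSet",
    "StressProtocol",
    "Trajectory",
    "DegenerateVariantError",
    "IntegrationError",
    "flux",
    "rhs",
    "unstressed_steady_state",
    "simulate",
    "classify_apoptosis",
    "load_params",
    "save_params",
]

#: Parameter names in Table-1 order; also the layout of the flat vectors
#: consumed by the compiled kernels.
PARAM_NAMES: tuple[str, ...] = (
    "S", "alpha_B", "beta_B", "gamma_B", "gamma_BC", "alpha_A", "beta_A",
    "phi_A", "alpha_M", "sigma_M", "gamma_M", "alpha_C", "sigma_C",
    "mu_C", "gamma_C", "phi_C", "sigma_J", "u_B", "u_M",
)

STATE_NAMES: tuple[str, ...] = ("B", "Bc", "A", "M", "C")

#: The representative-value column of Table 1 (the "R variant").
REPRESENTATIVE_VALUES: dict[str, float] = {
    "S": 1.0, "alpha_B": 1.0, "beta_B": 1.0, "gamma_B": 1.0,
    "gamma_BC": 1.0, "alpha_A": 1.0, "beta_A": 1.0, "phi_A": 10.0,
    "alpha_M": 1.0, "sigma_M": 50.0, "gamma_M": 1.0, "alpha_C": 0.005,
    "sigma_C": 0.001, "mu_C": 1.0, "gamma_C": 0.3, "phi_C": 0.15,
    "sigma_J": 0.01, "u_B": 1.0, "u_M": 1.0,
}


class DegenerateVariantError(ValueError):
    """No unstressed steady state exists for this parameter variant.

    ``reason`` is ``"flux_saturated"`` when resting autophagosome
    production exceeds the flux capacity (alpha_A * B >= beta_A * phi_A)
    or ``"zero_flux"`` when the resting flux is zero, leaving damaged
    mitochondria without a clearance balance.
    """

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


class IntegrationError(RuntimeError):
    """The ODE solver failed (step-size collapse)."""


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """One parameter variant ("cell"); defaults are the R variant."""

    S: float = 1.0
    alpha_B: float = 1.0
    beta_B: float = 1.0
    gamma_B: float = 1.0
    gamma_BC: float = 1.0
    alpha_A: float = 1.0
    beta_A: float = 1.0
    phi_A: float = 10.0
    alpha_M: float = 1.0
    sigma_M: float = 50.0
    gamma_M: float = 1.0
    alpha_C: float = 0.005
    sigma_C: float = 0.001
    mu_C: float = 1.0
    gamma_C: float = 0.3
    phi_C: float = 0.15
    sigma_J: float = 0.01
    u_B: float = 1.0
    u_M: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, "
                                 f"got {v!r}")
        if self.phi_C <= 0:
            raise ValueError("phi_C must be > 0")

    @classmethod
    def representative(cls) -> "ParameterSet":
        """The Table-1 representative-value column."""
        return cls(**REPRESENTATIVE_VALUES)

    def replace(self, **overrides: float) -> "ParameterSet":
        return dataclasses.replace(self, **overrides)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclasses.dataclass(frozen=True)
class StressProtocol:
    """Piecewise-constant ischemic stress: S(t) = level on [t_on, t_off)."""

    level: float
    t_on: float = 0.0
    t_off: float = 24.0
    horizon: float = 48.0

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("stress level must be >= 0")
        if not (0 <= self.t_on <= self.t_off <= self.horizon):
            raise ValueError("require 0 <= t_on <= t_off <= horizon")

    def stress_at(self, t: float) -> float:
        return self.level if self.t_on <= t < self.t_off else 0.0

    @classmethod
    def standard(cls, level: float) -> "StressProtocol":
        """Stress applied 0-24 h of a 48 h simulation."""
        return cls(level=level, t_on=0.0, t_off=24.0, horizon=48.0)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Time grid, state matrix (n, 5) and derived autophagic flux."""

    times: np.ndarray
    states: np.ndarray
    params: ParameterSet

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if y.shape != (t.size, len(STATE_NAMES)):
            raise ValueError("states must have shape (len(times), 5)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    @property
    def flux(self) -> np.ndarray:
        return flux(self.states[:, 2], self.params)

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def value_at(self, name: str, t: float) -> float:
        """Linear interpolation of one component on the stored grid."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"time {t} outside trajectory grid")
        return float(np.interp(t, self.times, self.component(name)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        df["J"] = self.flux
        return df


def flux(A, params: ParameterSet):
    """Saturable autophagic flux J(A) = beta_A * A / (1 + A / phi_A)."""
    A = np.asarray(A, dtype=float)
    return params.beta_A * A / (1.0 + A / params.phi_A)


def _check_state(state: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Validate a state vector, forgiving sub-tolerance float noise."""
    y = np.asarray(state, dtype=float).copy()
    if y.shape != (5,):
        raise ValueError("state must have 5 components (B, Bc, A, M, C)")
    for j in range(5):
        if y[j] < 0:
            if y[j] < -100 * atol:
                raise ValueError(
                    f"state component {STATE_NAMES[j]} is negative: {y[j]}")
            y[j] = 0.0
    if y[4] > 1.0:
        if y[4] > 1.0 + 100 * atol:
            raise ValueError(f"Caspase level exceeds 1: {y[4]}")
        y[4] = 1.0
    return y


def rhs(state: Sequence[float], t: float, params: ParameterSet,
        protocol: StressProtocol) -> np.ndarray:
    """Right-hand side (dB, dBc, dA, dM, dC) at time ``t``."""
    y = _check_state(np.asarray(state, dtype=float))
    if not (0 <= t <= protocol.horizon):
        raise ValueError(f"t={t} outside [0, {protocol.horizon}]")
    return _kernels.rhs(y, protocol.stress_at(t), params.to_array())


def unstressed_steady_state(params: ParameterSet,
                            residual_tol: float = 1e-8) -> np.ndarray:
    """Resting (S = 0) steady state with Caspase on its lowest stable branch.

    Solved by fixed-point iteration on the algebraic balances (resting
    flux equals autophagosome production) coupled to the lowest stable
    root of the Caspase balance.  Raises :class:`DegenerateVariantError`
    when no resting autophagosome or mitochondria balance exists.
    """
    p = params.to_array()
    y, status = _kernels.steady_state(p)
    if status == 1:
        raise DegenerateVariantError(
            "autophagosome production alpha_A*B exceeds the flux capacity "
            "beta_A*phi_A at rest; no finite resting A", "flux_saturated")
    if status == 2:
        raise DegenerateVariantError(
            "zero resting autophagic flux; damaged mitochondria have no "
            "clearance balance", "zero_flux")
    resid = _kernels.rhs(y, 0.0, p)
    if np.max(np.abs(resid)) > residual_tol:
        raise RuntimeError(
            f"steady-state residual {np.max(np.abs(resid)):.3g} exceeds "
            f"{residual_tol}; fixed-point iteration did not converge")
    return y


def simulate(params: ParameterSet, protocol: StressProtocol,
             init: Sequence[float] | None = None,
             grid: Iterable[float] | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model under a stress protocol.

    The integration is restarted at the stress discontinuities (t_on,
    t_off) so the solver never steps across them.  ``init`` defaults to
    the variant's unstressed steady state; ``grid`` defaults to a 0.1 h
    output grid over [0, horizon].
    """
    if init is None:
        y0 = unstressed_steady_state(params)
    else:
        y0 = _check_state(init)
    if grid is None:
        grid = np.arange(0.0, protocol.horizon + 1e-9, 0.1)
    t_eval = np.asarray(sorted(set(float(t) for t in grid)))
    if t_eval.size == 0 or t_eval[0] < 0 or t_eval[-1] > protocol.horizon:
        raise ValueError("grid must be non-empty and within [0, horizon]")

    p = params.to_array()
    breakpoints = sorted({0.0, protocol.t_on, protocol.t_off,
                          protocol.horizon})
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if b <= a:
            continue
        s = protocol.stress_at(0.5 * (a + b))
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        # Integrate to the segment endpoint even when the caller requested
        # no output there, so the next segment restarts from the true state.
        seg_t = np.union1d(seg_eval, [b])
        sol = solve_ivp(lambda t, yy: _kernels.rhs(yy, s, p), (a, b), y,
                        method=method, rtol=rtol, atol=atol,
                        t_eval=seg_t, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{a}, {b}]: {sol.message}")
        keep = np.isin(sol.t, seg_eval)
        if keep.any():
            times.append(sol.t[keep])
            states.append(sol.y.T[keep])
        y = _check_state(sol.y[:, -1], atol=atol)

    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    t_out, idx = np.unique(t_all, return_index=True)
    y_out = np.clip(y_all[idx], 0.0, None)
    y_out[:, 4] = np.minimum(y_out[:, 4], 1.0)
    return Trajectory(times=t_out, states=y_out, params=params)


def classify_apoptosis(traj: Trajectory, threshold: float = 0.5,
                       at: float | None = None) -> bool:
    """Apoptotic iff the Caspase-3 level strictly exceeds ``threshold``
    at time ``at`` (default: end of the trajectory)."""
    if at is None:
        at = float(traj.times[-1])
    return traj.value_at("C", at) > threshold


def save_params(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as flat YAML/JSON key-value pairs."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_params(path: str | Path) -> ParameterSet:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ParameterSet(**{k: float(v) for k, v in data.items()})
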