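"""Heat-shock protocols, ODE integration, and trajectory summaries.

A temperature upshift is modeled purely as a jump in the initial
unfolded-protein load: the UP equation has no production term, so shifting
cells from 25 C to a target temperature corresponds to starting the
integration from the basal state with ``up_free`` set by the exponential
temperature map. The system is stiff (client binding at k1 ~ 167 /(min a.u.)
versus reporter accumulation over hours), so the default solver is an
implicit stiff method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    DEFAULT_INITIAL,
    DEFAULT_TEMPERATURE_MAP,
    SPECIES,
    KineticParameters,
    ModelState,
    TemperatureMap,
    make_jacobian,
    make_rhs,
    up_from_temperature,
)

__all__ = [
    "Protocol",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "heat_shock",
    "complex_fraction",
    "integrate_fixed_rk4",
]

#: solver tolerances used for production simulations
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
DEFAULT_METHOD = "LSODA"  # stiff-capable (BDF switching); "Radau"/"BDF" also accepted


class IntegrationError(RuntimeError):
    """The ODE solver failed to complete the requested time span."""


@dataclass(frozen=True)
class Protocol:
    """A single temperature-upshift protocol.

    ``output_times`` defaults to a 0.5-min grid over ``duration`` (two-hour
    runs by default, matching the reporter time courses).
    """

    target_temp: float = 39.0
    basal_temp: float = 25.0
    duration: float = 120.0
    output_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if t.size == 0 or t[0] != 0.0:
                raise ValueError("output_times must start at 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError("output_times must be strictly increasing")
            if t[-1] > self.duration:
                raise ValueError("output_times must lie within [0, duration]")
            object.__setattr__(self, "output_times", tuple(t))

    @property
    def times(self) -> np.ndarray:
        if self.output_times is not None:
            return np.asarray(self.output_times, dtype=float)
        return np.arange(0.0, self.duration + 1e-9, 0.5)


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered solution of the model under one protocol.

    ``states`` is an (n_times, 6) array in :data:`heatshock.model.SPECIES`
    order; tiny solver undershoots are clipped to zero on construction.
    """

    times: np.ndarray
    states: np.ndarray
    protocol: Protocol
    params: KineticParameters
    solver_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if y.shape != (t.size, len(SPECIES)):
            raise ValueError(f"states shape {y.shape} does not match times {t.size}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", np.maximum(y, 0.0))

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def at(self, time: float) -> ModelState:
        """State at an output time (must be on the output grid)."""
        idx = np.flatnonzero(np.isclose(self.times, time))
        if idx.size == 0:
            raise KeyError(f"time {time} min is not on the output grid")
        return ModelState.from_array(self.states[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_min", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _integrate(
    params: KineticParameters,
    y0: np.ndarray,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
    method: str,
) -> np.ndarray:
    rhs = make_rhs(params)
    kwargs = {}
    if method in ("Radau", "BDF", "LSODA"):
        kwargs["jac"] = make_jacobian(params)
    sol = solve_ivp(
        rhs,
        (float(t_eval[0]), float(t_eval[-1])),
        np.asarray(y0, dtype=float),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        **kwargs,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver {method} failed: {sol.message}; last state {sol.y[:, -1] if sol.y.size else y0}"
        )
    out = sol.y.T.copy()
    if t_eval[0] == 0.0:
        out[0] = y0  # t=0 row is the initial condition, not the interpolant
    return out


def simulate(
    params: KineticParameters,
    init: ModelState,
    protocol: Protocol,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the six-ODE model over ``protocol`` from ``init``.

    Deterministic given identical inputs and tolerances. Raises
    :class:`IntegrationError` with the solver's diagnostic message on
    failure (e.g. step-size underflow).
    """
    t_eval = protocol.times
    states = _integrate(params, init.as_array(), t_eval, rtol, atol, method)
    return Trajectory(
        times=t_eval,
        states=states,
        protocol=protocol,
        params=params,
        solver_meta={"method": method, "rtol": rtol, "atol": atol},
    )


def heat_shock(
    params: KineticParameters,
    target_temp: float = 39.0,
    duration: float = 120.0,
    *,
    init: ModelState | None = None,
    temperature_map: TemperatureMap = DEFAULT_TEMPERATURE_MAP,
    output_times: Sequence[float] | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Simulate an upshift from 25 C to ``target_temp``.

    Builds the basal initial state with ``up_free`` replaced by the
    temperature map's value at ``target_temp`` and integrates for
    ``duration`` minutes.
    """
    base = init if init is not None else DEFAULT_INITIAL
    up0 = up_from_temperature(target_temp, temperature_map)
    start = base.replace(up_free=up0)
    protocol = Protocol(
        target_temp=target_temp,
        duration=duration,
        output_times=tuple(output_times) if output_times is not None else None,
    )
    return simulate(params, start, protocol, rtol=rtol, atol=atol, method=method)


def complex_fraction(traj: Trajectory) -> np.ndarray:
    """Hsp70*Hsf1 complex level normalized to its basal (t=0) value.

    This is the model-side analogue of the IP/MS readout: the amount of
    Hsp70 co-precipitating with Hsf1, relative to the pre-shock baseline.
    """
    c = traj.species("hsp_hsf1")
    if c[0] <= 0:
        raise ValueError("cannot normalize: basal hsp_hsf1 complex is zero")
    return c / c[0]


def integrate_fixed_rk4(
    params: KineticParameters,
    init: ModelState,
    t_end: float,
    step: float = 1e-3,
    output_times: Sequence[float] | None = None,
) -> Trajectory:
    """Fixed-step classical Runge-Kutta (RK4) integration.

    A deliberately simple non-adaptive integrator kept as an independent
    cross-check of the stiff solver; ``step`` must resolve the fastest
    binding timescale (default 0.001 min does for the published
    parameters). Output is sampled at ``output_times`` (default: every
    0.5 min), each rounded to the nearest step.
    """
    rhs = make_rhs(params)
    if output_times is None:
        output_times = np.arange(0.0, t_end + 1e-9, 0.5)
    out_t = np.asarray(output_times, dtype=float)
    n_steps = int(round(t_end / step))
    out_idx = np.round(out_t / step).astype(int)
    if out_idx[-1] > n_steps:
        raise ValueError("output_times exceed t_end")
    want = {}
    for j, idx in enumerate(out_idx):
        want.setdefault(int(idx), []).append(j)

    y = list(init.as_array())
    h = step
    out = np.empty((out_t.size, len(SPECIES)))
    if 0 in want:
        for j in want[0]:
            out[j] = y
    for i in range(1, n_steps + 1):
        t = (i - 1) * h
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * h, [y[m] + 0.5 * h * k1[m] for m in range(6)])
        k3 = rhs(t + 0.5 * h, [y[m] + 0.5 * h * k2[m] for m in range(6)])
        k4 = rhs(t + h, [y[m] + h * k3[m] for m in range(6)])
        y = [
            y[m] + (h / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            for m in range(6)
        ]
        if i in want:
            for j in want[i]:
                out[j] = y
    protocol = Protocol(duration=t_end, output_times=tuple(out_t))
    return Trajectory(
        times=out_t,
        states=out,
        protocol=protocol,
        params=params,
        solver_meta={"method": "rk4-fixed", "step": step},
    )
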