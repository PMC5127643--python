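"""Synthetic perturbations of the feedback loop.

Three extensions of the base model:

* **decoy** -- two extra species, a free Hsf1 decoy and its Hsp70-bound
  form. The decoy binds Hsp70 with the same kinetics as Hsf1 (on-rate k1,
  off-rate k2) but cannot bind DNA, so it contributes nothing to the Hill
  terms; it activates endogenous Hsf1 purely by titrating Hsp70.
* **dose response** -- final reporter output as a function of the initial
  amount of overexpressed full-length Hsf1 (which both binds Hsp70 and
  drives transcription) or of the decoy (which only binds Hsp70).
* **phosphorylation gain** -- the transcriptional activation rate beta
  evolves sigmoidally in time from a pre-phosphorylated to a phosphorylated
  value, modeling the slow second phase of Hsf1 activity; the
  phospho-dead variant is the degenerate constant gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    DEFAULT_INITIAL,
    SPECIES,
    KineticParameters,
    ModelState,
    ParameterError,
    StateError,
    make_rhs,
)
from .simulate import (
    DEFAULT_ATOL,
    DEFAULT_METHOD,
    DEFAULT_RTOL,
    IntegrationError,
    Protocol,
    Trajectory,
)

__all__ = [
    "DECOY_SPECIES",
    "DecoyState",
    "PhosphoGain",
    "decoy_derivatives",
    "simulate_decoy",
    "dose_response",
    "phospho_gain_at",
    "simulate_phospho",
]

DECOY_SPECIES = SPECIES + ("decoy_free", "hsp_decoy")


@dataclass(frozen=True)
class DecoyState:
    """Eight-species state: the six base species plus the decoy pair."""

    hsp_free: float = 1.0
    hsf1_free: float = 0.0
    up_free: float = 0.52
    hsp_hsf1: float = 1.0 / 500.0
    hsp_up: float = 0.0
    yfp: float = 3.0
    decoy_free: float = 0.0
    hsp_decoy: float = 0.0

    def __post_init__(self) -> None:
        for name in DECOY_SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise StateError(f"species {name!r} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in DECOY_SPECIES], dtype=float)

    @classmethod
    def from_base(cls, base: ModelState, decoy_free: float = 0.0,
                  hsp_decoy: float = 0.0) -> "DecoyState":
        return cls(**{s: getattr(base, s) for s in SPECIES},
                   decoy_free=decoy_free, hsp_decoy=hsp_decoy)

    @property
    def total_decoy(self) -> float:
        return self.decoy_free + self.hsp_decoy


def _make_decoy_rhs(params: KineticParameters):
    base_rhs = make_rhs(params)
    k1, k2 = params.k1, params.k2

    def rhs(t: float, y):
        d = base_rhs(t, y)
        hsp = y[0] if y[0] > 0.0 else 0.0
        dec = y[6] if y[6] > 0.0 else 0.0
        c_dec = y[7] if y[7] > 0.0 else 0.0
        bind = k1 * hsp * dec
        unbind = k2 * c_dec
        return [
            d[0] + unbind - bind,
            d[1], d[2], d[3], d[4], d[5],
            unbind - bind,
            bind - unbind,
        ]

    return rhs


def decoy_derivatives(
    state: DecoyState, params: KineticParameters, clip_tol: float = 1e-12
) -> np.ndarray:
    """Per-species rates for the eight-species decoy model.

    With zero total decoy the first six components equal the base model's
    derivatives exactly; the decoy pair is conserved (bind/unbind only).
    """
    y = state.as_array() if isinstance(state, DecoyState) else np.asarray(state, float)
    if np.any(y < -clip_tol):
        raise StateError(f"negative species concentration beyond clip tolerance: {y}")
    return np.array(_make_decoy_rhs(params)(0.0, y), dtype=float)


def simulate_decoy(
    params: KineticParameters,
    init: DecoyState,
    protocol: Protocol,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the decoy-extended model; states are (n_times, 8)."""
    t_eval = protocol.times
    sol = solve_ivp(
        _make_decoy_rhs(params), (float(t_eval[0]), float(t_eval[-1])),
        init.as_array(), method=method, t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"decoy simulation failed: {sol.message}")
    states = np.maximum(sol.y.T, 0.0)
    if t_eval[0] == 0.0:
        states[0] = init.as_array()
    return _DecoyTrajectory(
        times=t_eval, states=states, protocol=protocol, params=params,
        solver_meta={"method": method, "rtol": rtol, "atol": atol},
    )


@dataclass(frozen=True)
class _DecoyTrajectory(Trajectory):
    """Trajectory over the eight decoy-model species."""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if y.shape != (t.size, len(DECOY_SPECIES)):
            raise ValueError(f"states shape {y.shape} does not match times {t.size}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", np.maximum(y, 0.0))

    def species(self, name: str) -> np.ndarray:
        return self.states[:, DECOY_SPECIES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(DECOY_SPECIES))
        df.insert(0, "time_min", self.times)
        return df


def dose_response(
    species: str,
    levels: Sequence[float],
    params: KineticParameters,
    protocol: Protocol | None = None,
    *,
    init: ModelState = DEFAULT_INITIAL,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> pd.DataFrame:
    """Final reporter level versus initial overexpression level.

    ``species`` is ``"full_length_hsf1"`` (added amount starts free and
    increments total Hsf1, feeding both Hsp70 binding and the Hill term) or
    ``"decoy"`` (increments total decoy only). The default protocol is a
    basal 25 C run -- overexpression activates the reporter without any
    temperature upshift. Returns a frame with columns ``level`` and
    ``final_yfp``.
    """
    if species not in ("full_length_hsf1", "decoy"):
        raise ValueError(
            f"unknown species {species!r}: expected 'full_length_hsf1' or 'decoy'"
        )
    lv = [float(x) for x in levels]
    if any(x < 0 for x in lv) or any(b > a for a, b in zip(lv[1:], lv)):
        raise ValueError("levels must be non-negative and non-decreasing")
    if protocol is None:
        protocol = Protocol(target_temp=25.0, duration=120.0)
    rows = []
    for level in lv:
        if species == "full_length_hsf1":
            start = DecoyState.from_base(
                init.replace(hsf1_free=init.hsf1_free + level)
            )
        else:
            start = DecoyState.from_base(init, decoy_free=level)
        traj = simulate_decoy(params, start, protocol,
                              rtol=rtol, atol=atol, method=method)
        rows.append({"level": level, "final_yfp": float(traj.species("yfp")[-1])})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhosphoGain:
    """Sigmoidal time course of the transcriptional activation rate.

    beta(t) = beta_initial + (beta_final - beta_initial) /
              (1 + exp(-steepness * (t - midpoint_time)))

    Defaults: midpoint 20 min (phosphorylation peaks ~20 min after
    upshift), steepness 0.3 /min, and a two-fold gain over the base rate.
    The phospho-dead variant is ``beta_final == beta_initial``.
    """

    beta_initial: float = 1.778
    beta_final: float = 3.556
    midpoint_time: float = 20.0
    steepness: float = 0.3

    def __post_init__(self) -> None:
        if self.beta_initial <= 0 or self.beta_final <= 0:
            raise ParameterError("beta_initial and beta_final must be > 0")
        if self.steepness <= 0:
            raise ParameterError("steepness must be > 0")

    def constant(self) -> "PhosphoGain":
        """Degenerate gain pinned at ``beta_initial`` (phospho-dead)."""
        return PhosphoGain(
            beta_initial=self.beta_initial, beta_final=self.beta_initial,
            midpoint_time=self.midpoint_time, steepness=self.steepness,
        )


def phospho_gain_at(t: float, gain: PhosphoGain) -> float:
    """Instantaneous beta (1/min) at time ``t`` minutes after upshift."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    db = gain.beta_final - gain.beta_initial
    return gain.beta_initial + db / (
        1.0 + math.exp(-gain.steepness * (t - gain.midpoint_time))
    )


def simulate_phospho(
    params: KineticParameters,
    gain: PhosphoGain,
    protocol: Protocol,
    *,
    init: ModelState = DEFAULT_INITIAL,
    apply_to_hsp_synthesis: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Base model with the reporter's beta replaced by the phospho gain.

    By default the time-varying gain drives only the reporter's
    transcription while Hsp70 synthesis keeps the constant base rate
    ``gain.beta_initial``: phosphorylation then adds reporter output
    monotonically, producing the sustained late-phase activity seen in
    wild-type cells but not in the phospho-dead variant. Routing the gain
    into Hsp70 synthesis as well (``apply_to_hsp_synthesis=True``) lets
    the extra chaperone feed back, re-repress Hsf1 faster and largely
    cancel the gain -- that variant loses the sustained-activity
    signature and is kept only for exploration.

    A constant gain at the base beta reproduces
    :func:`heatshock.simulate.simulate` within solver tolerance.
    """
    k1, k2, k3, k4, k5 = params.k1, params.k2, params.k3, params.k4, params.k5
    Kd, n, kdil = params.Kd, params.n, params.kdil
    beta_hsp = gain.beta_initial

    def rhs(t: float, y):
        hsp = y[0] if y[0] > 0.0 else 0.0
        hsf1 = y[1] if y[1] > 0.0 else 0.0
        up = y[2] if y[2] > 0.0 else 0.0
        c_hf = y[3] if y[3] > 0.0 else 0.0
        c_up = y[4] if y[4] > 0.0 else 0.0
        yfp = y[5] if y[5] > 0.0 else 0.0
        bind_hf = k1 * hsp * hsf1
        unbind_hf = k2 * c_hf
        bind_up = k3 * hsp * up
        unbind_up = k4 * c_up
        degrade = k5 * c_up
        if hsf1 > 0.0:
            r = (hsf1 / Kd) ** n
            hill_unit = r / (1.0 + r)
        else:
            hill_unit = 0.0
        b = phospho_gain_at(t, gain)
        hill_hsp = (b if apply_to_hsp_synthesis else beta_hsp) * hill_unit
        hill_yfp = b * hill_unit
        return [
            unbind_hf - bind_hf + unbind_up + degrade - bind_up + hill_hsp,
            unbind_hf - bind_hf,
            unbind_up - bind_up,
            bind_hf - unbind_hf,
            bind_up - unbind_up - degrade,
            hill_yfp - kdil * yfp,
        ]

    t_eval = protocol.times
    sol = solve_ivp(
        rhs, (float(t_eval[0]), float(t_eval[-1])), init.as_array(),
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"phospho simulation failed: {sol.message}")
    states = sol.y.T.copy()
    if t_eval[0] == 0.0:
        states[0] = init.as_array()
    return Trajectory(
        times=t_eval, states=states, protocol=protocol, params=params,
        solver_meta={"method": method, "rtol": rtol, "atol": atol,
                     "gain": gain.__dict__.copy()},
    )
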