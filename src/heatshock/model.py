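"""Core species, parameters and kinetics of the Hsp70-Hsf1 titration feedback loop.

The model tracks six species in arbitrary concentration units (a.u.) with
time in minutes: free Hsp70 chaperone, free Hsf1 transcription factor, free
unfolded protein (UP), the repressive Hsp70*Hsf1 complex, the Hsp70*UP
client complex, and a YFP reporter of Hsf1 transcriptional activity.

Free Hsp70 sequesters Hsf1 in an inactive complex; heat-denatured clients
(UP) compete for Hsp70 and titrate it away, releasing Hsf1, which drives
cooperative (Hill, n=3) transcription of both Hsp70 and the reporter --
closing a negative feedback loop. Hsp70 cannot bind Hsf1 and UP
simultaneously, and the two clients share the same on-rate constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "SPECIES",
    "ModelState",
    "KineticParameters",
    "TemperatureMap",
    "ParameterError",
    "StateError",
    "up_from_temperature",
    "hill_rate",
    "derivatives",
    "DEFAULT_PARAMS",
    "DEFAULT_INITIAL",
    "DEFAULT_TEMPERATURE_MAP",
]

#: canonical species order used by every array interface in the package
SPECIES = ("hsp_free", "hsf1_free", "up_free", "hsp_hsf1", "hsp_up", "yfp")


class ParameterError(ValueError):
    """Invalid kinetic parameter value."""


class StateError(ValueError):
    """Invalid model state (e.g. negative concentration)."""


@dataclass(frozen=True)
class ModelState:
    """Concentrations of the six model species at one time point (a.u.).

    Attributes
    ----------
    hsp_free : free Hsp70 chaperone
    hsf1_free : free (transcriptionally competent) Hsf1
    up_free : free unfolded protein
    hsp_hsf1 : repressive Hsp70*Hsf1 complex
    hsp_up : Hsp70*UP client complex
    yfp : HSE-YFP reporter
    """

    hsp_free: float = 1.0
    hsf1_free: float = 0.0
    up_free: float = 0.52
    hsp_hsf1: float = 1.0 / 500.0
    hsp_up: float = 0.0
    yfp: float = 3.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise StateError(
                    f"species {f.name!r} must be finite and >= 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise StateError(f"expected {len(SPECIES)} species, got shape {y.shape}")
        return cls(**dict(zip(SPECIES, y)))

    @property
    def total_hsf1(self) -> float:
        """Total Hsf1 (free + Hsp70-bound); conserved by the dynamics."""
        return self.hsf1_free + self.hsp_hsf1

    @property
    def total_hsp(self) -> float:
        """Total Hsp70 (free + both complexes)."""
        return self.hsp_free + self.hsp_hsf1 + self.hsp_up

    def replace(self, **kwargs: float) -> "ModelState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and transcriptional parameters of the feedback loop.

    Defaults are the published selected set. ``k1`` and ``k3`` are the
    Hsp70 on-rate constants for its two clients (Hsf1 and UP); the model
    assumes they are equal, so constructing with ``k1 != k3`` raises unless
    ``allow_unequal_on_rates=True``.

    ``beta_yfp``/``Kd_yfp``/``n_yfp`` optionally decouple the reporter's
    Hill function from Hsp70 synthesis; by default both share ``beta``,
    ``Kd`` and ``n`` (one Hill function drives both outputs).
    """

    k1: float = 166.8      # client*Hsp70 on-rate constant, 1/(min*a.u.)
    k2: float = 2.783      # Hsp70*Hsf1 off-rate, 1/min
    k3: float = 166.8      # Hsp70*UP on-rate constant, 1/(min*a.u.)
    k4: float = 0.0464     # Hsp70*UP off-rate, 1/min
    k5: float = 4.64e-7    # UP degradation rate out of the complex, 1/min
    beta: float = 1.778    # transcriptional activation rate, 1/min
    Kd: float = 0.0022     # Hsf1-DNA dissociation constant, a.u.
    kdil: float = 0.0      # YFP dilution rate, 1/min (fixed 0: short courses)
    n: int = 3             # Hill coefficient (fixed: Hsf1 trimer)
    allow_unequal_on_rates: bool = False
    beta_yfp: float | None = None
    Kd_yfp: float | None = None
    n_yfp: int | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "beta", "kdil"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"rate {name!r} must be finite and >= 0, got {v!r}")
        if not (math.isfinite(self.Kd) and self.Kd > 0):
            raise ParameterError(f"Kd must be > 0, got {self.Kd!r}")
        for name in ("n", "n_yfp"):
            v = getattr(self, name)
            if v is None:
                continue
            if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)) or v < 1:
                raise ParameterError(
                    f"Hill coefficient {name!r} must be a positive integer, got {v!r}"
                )
        if self.beta_yfp is not None and self.beta_yfp < 0:
            raise ParameterError("beta_yfp must be >= 0")
        if self.Kd_yfp is not None and self.Kd_yfp <= 0:
            raise ParameterError("Kd_yfp must be > 0")
        if self.k1 != self.k3 and not self.allow_unequal_on_rates:
            raise ParameterError(
                "model assumes equal client on-rates (k1 == k3); pass "
                "allow_unequal_on_rates=True to override"
            )

    @property
    def yfp_hill(self) -> tuple[float, float, int]:
        """(beta, Kd, n) effective for the reporter's Hill term."""
        return (
            self.beta if self.beta_yfp is None else self.beta_yfp,
            self.Kd if self.Kd_yfp is None else self.Kd_yfp,
            self.n if self.n_yfp is None else self.n_yfp,
        )

    def replace(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


DEFAULT_PARAMS = KineticParameters()
DEFAULT_INITIAL = ModelState()


@dataclass(frozen=True)
class TemperatureMap:
    """Exponential map from temperature to the initial unfolded-protein load.

    [UP](T) = A*exp(b*T), with A and b fixed by two anchor points: a small
    basal load at 25 C and the screened value at 39 C. Calorimetry supports
    an exponential dependence of unfolding on temperature in the 25-50 C
    range, which is the validity domain enforced here.
    """

    t_ref_low: float = 25.0
    up_ref_low: float = 0.52
    t_ref_high: float = 39.0
    up_ref_high: float = 10.51
    t_min: float = 25.0
    t_max: float = 50.0

    def __post_init__(self) -> None:
        if not (self.up_ref_high > self.up_ref_low > 0):
            raise ParameterError("anchors must satisfy up_ref_high > up_ref_low > 0")
        if not (self.t_ref_high > self.t_ref_low):
            raise ParameterError("anchors must satisfy t_ref_high > t_ref_low")

    @property
    def rate(self) -> float:
        """Exponential slope b (per deg C)."""
        return math.log(self.up_ref_high / self.up_ref_low) / (
            self.t_ref_high - self.t_ref_low
        )

    @property
    def amplitude(self) -> float:
        """Prefactor A (a.u.)."""
        return self.up_ref_low * math.exp(-self.rate * self.t_ref_low)


DEFAULT_TEMPERATURE_MAP = TemperatureMap()


def up_from_temperature(
    temp_C: float, temperature_map: TemperatureMap = DEFAULT_TEMPERATURE_MAP
) -> float:
    """Initial unfolded-protein concentration (a.u.) at ``temp_C``.

    Raises
    ------
    ValueError
        If ``temp_C`` lies outside the map's validity interval.
    """
    m = temperature_map
    if not (m.t_min <= temp_C <= m.t_max):
        raise ValueError(
            f"temperature {temp_C} degC outside the map's valid interval "
            f"[{m.t_min}, {m.t_max}] degC"
        )
    return m.amplitude * math.exp(m.rate * temp_C)


def hill_rate(hsf1_free: float, beta: float, Kd: float, n: int) -> float:
    """Transcription rate beta * [Hsf1]^n / (Kd^n + [Hsf1]^n) (a.u./min).

    Cooperative activation by free Hsf1 (trimer => n = 3 by default);
    bounded by ``beta`` and half-maximal at ``hsf1_free == Kd``.
    """
    if Kd <= 0:
        raise ParameterError(f"Kd must be > 0, got {Kd!r}")
    if hsf1_free < 0:
        raise StateError(f"hsf1_free must be >= 0, got {hsf1_free!r}")
    if hsf1_free == 0.0:
        return 0.0
    # evaluate via the ratio for numerical robustness at small Kd
    r = (hsf1_free / Kd) ** n
    return beta * r / (1.0 + r)


def make_rhs(params: KineticParameters, clip_tol: float = 1e-12):
    """Return a fast ``f(t, y) -> list[float]`` right-hand side.

    Solver round-off can push concentrations slightly negative; values are
    clipped to 0 before evaluating mass-action terms (undershoot beyond
    ``clip_tol`` is still clipped -- the tolerance only governs the strict
    validation done by :func:`derivatives`).
    """
    k1, k2, k3, k4, k5 = params.k1, params.k2, params.k3, params.k4, params.k5
    beta, Kd, n, kdil = params.beta, params.Kd, params.n, params.kdil
    beta_y, Kd_y, n_y = params.yfp_hill

    def rhs(t: float, y) -> list[float]:
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
            hill = beta * r / (1.0 + r)
            if beta_y == beta and Kd_y == Kd and n_y == n:
                hill_y = hill
            else:
                ry = (hsf1 / Kd_y) ** n_y
                hill_y = beta_y * ry / (1.0 + ry)
        else:
            hill = hill_y = 0.0

        return [
            unbind_hf - bind_hf + unbind_up + degrade - bind_up + hill,
            unbind_hf - bind_hf,
            unbind_up - bind_up,
            bind_hf - unbind_hf,
            bind_up - unbind_up - degrade,
            hill_y - kdil * yfp,
        ]

    return rhs


def make_jacobian(params: KineticParameters):
    """Analytic Jacobian ``J(t, y)`` of the clipped right-hand side."""
    k1, k2, k3, k4, k5 = params.k1, params.k2, params.k3, params.k4, params.k5
    beta, Kd, n, kdil = params.beta, params.Kd, params.n, params.kdil
    beta_y, Kd_y, n_y = params.yfp_hill

    def jac(t: float, y) -> np.ndarray:
        hsp = max(y[0], 0.0)
        hsf1 = max(y[1], 0.0)
        up = max(y[2], 0.0)

        def dhill(b: float, kd: float, nn: int) -> float:
            if hsf1 <= 0.0:
                return 0.0 if nn > 1 else b / kd
            r = (hsf1 / kd) ** nn
            return b * nn * r / (hsf1 * (1.0 + r) ** 2)

        dh = dhill(beta, Kd, n)
        dh_y = dhill(beta_y, Kd_y, n_y)

        J = np.zeros((6, 6))
        # rows: hsp, hsf1, up, hsp_hsf1, hsp_up, yfp
        J[0, 0] = -k1 * hsf1 - k3 * up
        J[0, 1] = -k1 * hsp + dh
        J[0, 2] = -k3 * hsp
        J[0, 3] = k2
        J[0, 4] = k4 + k5
        J[1, 0] = -k1 * hsf1
        J[1, 1] = -k1 * hsp
        J[1, 3] = k2
        J[2, 0] = -k3 * up
        J[2, 2] = -k3 * hsp
        J[2, 4] = k4
        J[3, 0] = k1 * hsf1
        J[3, 1] = k1 * hsp
        J[3, 3] = -k2
        J[4, 0] = k3 * up
        J[4, 2] = k3 * hsp
        J[4, 4] = -(k4 + k5)
        J[5, 1] = dh_y
        J[5, 5] = -kdil
        return J

    return jac


def derivatives(
    state: ModelState, params: KineticParameters, clip_tol: float = 1e-12
) -> np.ndarray:
    """Per-species rates (a.u./min) in :data:`SPECIES` order.

    The equations conserve total Hsf1 exactly (no Hsf1 synthesis or decay),
    change total Hsp70 only through Hill-driven synthesis, and remove UP
    only by degradation out of the Hsp70*UP complex (rate ``k5``), which
    simultaneously frees Hsp70 (release at ``k4 + k5``).
    """
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if np.any(y < -clip_tol):
        raise StateError(f"negative species concentration beyond clip tolerance: {y}")
    return np.array(make_rhs(params, clip_tol)(0.0, y), dtype=float)
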