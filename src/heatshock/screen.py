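"""Constraint-based parameter grid screening.

Candidate parameter sets are accepted or rejected against three features of
the measured Hsp70 dissociation kinetics:

1. basal binding -- at 25 C, Hsf1 stays mostly Hsp70-bound (the bound
   fraction of total Hsf1 never drops below ``basal_bound_min``);
2. dissociation -- after a 25->39 C upshift the Hsp70*Hsf1 complex falls
   to <= ``dissoc_threshold`` of its basal level within ``dissoc_time``;
3. re-association -- the complex recovers to >= ``reassoc_threshold`` of
   its basal level by ``reassoc_deadline``.

The screen enumerates the full cartesian product of per-parameter value
lists (log-spaced by default, since the published rates span nine orders of
magnitude) and reports, per surviving value of each parameter, the fraction
of successful sets that contain it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_INITIAL, DEFAULT_PARAMS, KineticParameters, ModelState
from .simulate import IntegrationError, complex_fraction, heat_shock

__all__ = [
    "FREE_PARAMETERS",
    "ParameterGrid",
    "ConstraintSpec",
    "ScreenResult",
    "check_constraints",
    "grid_screen",
    "value_frequencies",
    "default_grid",
]

#: parameters varied by the screen; k3 is slaved to k1 (shared client on-rate)
FREE_PARAMETERS = ("k1", "k2", "k4", "k5", "beta", "Kd")

# screening runs at looser tolerance than production simulation, for throughput
SCREEN_RTOL = 1e-5
SCREEN_ATOL = 1e-8

_BASAL_TIMES = tuple(np.arange(0.0, 120.0 + 1e-9, 5.0))
_UPSHIFT_TIMES = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 60.0)


@dataclass(frozen=True)
class ConstraintSpec:
    """Thresholds and deadlines for the three screening constraints.

    ``basal_bound_min`` quantifies "Hsf1 is Hsp70-bound in basal
    conditions" as a majority-bound requirement (the weakest reading
    consistent with the qualitative statement); the other thresholds are
    the published 10%/90% dissociation/re-association criteria.
    """

    basal_bound_min: float = 0.5
    dissoc_threshold: float = 0.10
    dissoc_time: float = 5.0
    reassoc_threshold: float = 0.90
    reassoc_deadline: float = 60.0
    basal_temp: float = 25.0
    shock_temp: float = 39.0

    def __post_init__(self) -> None:
        # thresholds are independent: dissoc_threshold = 1 or
        # reassoc_threshold = 0 are legal (vacuous) settings
        if not (0.0 < self.dissoc_threshold <= 1.0):
            raise ValueError("dissoc_threshold must be in (0, 1]")
        if not (0.0 <= self.reassoc_threshold <= 1.0):
            raise ValueError("reassoc_threshold must be in [0, 1]")
        if not (0.0 <= self.basal_bound_min <= 1.0):
            raise ValueError("basal_bound_min must be in [0, 1]")


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered value lists for each free parameter of the screen.

    ``values`` maps each name in :data:`FREE_PARAMETERS` to a non-empty
    list of positive values; ``n`` and ``kdil`` stay fixed.
    """

    values: Mapping[str, Sequence[float]]
    n: int = 3
    kdil: float = 0.0

    def __post_init__(self) -> None:
        missing = set(FREE_PARAMETERS) - set(self.values)
        extra = set(self.values) - set(FREE_PARAMETERS)
        if missing or extra:
            raise ValueError(
                f"grid must specify exactly {FREE_PARAMETERS}; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        vals = {}
        for name in FREE_PARAMETERS:
            v = tuple(float(x) for x in self.values[name])
            if len(v) == 0:
                raise ValueError(f"grid list for {name!r} is empty")
            if any(x <= 0 for x in v):
                raise ValueError(f"grid values for {name!r} must be > 0")
            vals[name] = v
        object.__setattr__(self, "values", vals)

    @property
    def size(self) -> int:
        return math.prod(len(v) for v in self.values.values())

    def combinations(self) -> Iterable[KineticParameters]:
        lists = [self.values[name] for name in FREE_PARAMETERS]
        for combo in itertools.product(*lists):
            d = dict(zip(FREE_PARAMETERS, combo))
            yield KineticParameters(
                k1=d["k1"], k2=d["k2"], k3=d["k1"], k4=d["k4"], k5=d["k5"],
                beta=d["beta"], Kd=d["Kd"], n=self.n, kdil=self.kdil,
            )


def default_grid(n_values: int = 5, decades: float = 2.0) -> ParameterGrid:
    """Log-spaced grid bracketing the published set by ``decades`` each way.

    The original screen's exact per-parameter ranges are not published
    numerically; this grid is a documented approximation centered on the
    selected values (``n_values`` odd keeps them on the grid).
    """
    values = {}
    offsets = np.linspace(-decades, decades, n_values)
    for name in FREE_PARAMETERS:
        center = getattr(DEFAULT_PARAMS, name)
        # center * 10**0.0 keeps the published value exactly on the grid
        values[name] = [center * 10.0 ** e for e in offsets]
    return ParameterGrid(values=values)


@dataclass(frozen=True)
class ScreenResult:
    """Per-set constraint flags plus success summaries.

    ``records`` has one row per parameter set: the six free-parameter
    values, boolean columns ``basal_bound``, ``dissociates``,
    ``reassociates``, ``passed``, and an ``error`` column holding the
    integration failure message for sets the solver could not handle
    (those count as failed).
    """

    records: pd.DataFrame
    spec: ConstraintSpec

    @property
    def success_count(self) -> int:
        return int(self.records["passed"].sum())

    @property
    def total(self) -> int:
        return len(self.records)

    def successful(self) -> pd.DataFrame:
        return self.records[self.records["passed"]]

    def frequencies(self) -> pd.DataFrame:
        return value_frequencies(self)

    def summary(self) -> str:
        lines = [
            "Parameter screen summary",
            "========================",
            f"parameter sets screened : {self.total}",
            f"successful sets         : {self.success_count}",
            f"basal-bound failures    : {int((~self.records['basal_bound']).sum())}",
            f"dissociation failures   : {int((~self.records['dissociates']).sum())}",
            f"re-association failures : {int((~self.records['reassociates']).sum())}",
        ]
        if self.success_count:
            freq = self.frequencies()
            lines.append("")
            lines.append("% of successful sets containing each value:")
            lines.append(freq.to_string(index=False))
        return "\n".join(lines)


def check_constraints(
    params: KineticParameters,
    spec: ConstraintSpec = ConstraintSpec(),
    init: ModelState = DEFAULT_INITIAL,
    *,
    rtol: float = SCREEN_RTOL,
    atol: float = SCREEN_ATOL,
) -> dict:
    """Evaluate the three screening constraints for one parameter set.

    Runs a basal trajectory at ``spec.basal_temp`` and an upshift to
    ``spec.shock_temp``; integration failures are reported in the returned
    record (``error`` key), not raised, so a sweep survives pathological
    corners of the grid.
    """
    rec = {
        "basal_bound": False,
        "dissociates": False,
        "reassociates": False,
        "passed": False,
        "error": "",
    }
    try:
        basal = heat_shock(
            params, spec.basal_temp, 120.0, init=init,
            output_times=_BASAL_TIMES, rtol=rtol, atol=atol,
        )
        total_hsf1 = init.total_hsf1
        bound_frac = basal.species("hsp_hsf1") / total_hsf1
        rec["basal_bound"] = bool(bound_frac.min() >= spec.basal_bound_min)

        upshift_times = tuple(
            sorted({0.0, *np.arange(0.5, spec.dissoc_time + 1e-9, 0.5),
                    spec.reassoc_deadline})
        )
        shock = heat_shock(
            params, spec.shock_temp, spec.reassoc_deadline, init=init,
            output_times=upshift_times, rtol=rtol, atol=atol,
        )
        frac = complex_fraction(shock)
        in_window = shock.times <= spec.dissoc_time + 1e-9
        rec["dissociates"] = bool(frac[in_window].min() <= spec.dissoc_threshold)
        rec["reassociates"] = bool(frac[-1] >= spec.reassoc_threshold)
        rec["passed"] = rec["basal_bound"] and rec["dissociates"] and rec["reassociates"]
    except (IntegrationError, ValueError) as exc:
        rec["error"] = str(exc)
    return rec


def grid_screen(
    grid: ParameterGrid,
    spec: ConstraintSpec = ConstraintSpec(),
    init: ModelState = DEFAULT_INITIAL,
    *,
    rtol: float = SCREEN_RTOL,
    atol: float = SCREEN_ATOL,
    progress: bool = False,
) -> ScreenResult:
    """Screen every combination in ``grid`` against ``spec``.

    Deterministic and enumeration-order independent (one record per
    combination, keyed by the parameter values themselves).
    """
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    rows = []
    it = grid.combinations()
    if progress:
        from tqdm import tqdm  # optional nicety; screen works without it

        it = tqdm(it, total=grid.size, desc="screening")
    for params in it:
        rec = {name: getattr(params, name) for name in FREE_PARAMETERS}
        rec.update(check_constraints(params, spec, init, rtol=rtol, atol=atol))
        rows.append(rec)
    records = pd.DataFrame(rows)
    return ScreenResult(records=records, spec=spec)


def value_frequencies(result: ScreenResult) -> pd.DataFrame:
    """Percentage of successful sets containing each grid value.

    Returns a tidy frame (parameter, value, frequency_pct). With zero
    successful sets the frequencies are undefined: every ``frequency_pct``
    is NaN and the ``undefined`` column is True, rather than reporting 0%.
    """
    if result.total == 0:
        raise ValueError("empty screen result")
    ok = result.successful()
    rows = []
    for name in FREE_PARAMETERS:
        for value in sorted(result.records[name].unique()):
            if len(ok) == 0:
                pct = float("nan")
            else:
                pct = 100.0 * (ok[name] == value).sum() / len(ok)
            rows.append(
                {"parameter": name, "value": value, "frequency_pct": pct,
                 "undefined": len(ok) == 0}
            )
    return pd.DataFrame(rows)
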