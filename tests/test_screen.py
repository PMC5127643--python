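"""Constraint checks, grid enumeration and success-frequency accounting."""

import numpy as np
import pandas as pd
import pytest

from heatshock import (
    DEFAULT_PARAMS,
    ConstraintSpec,
    KineticParameters,
    ParameterGrid,
    check_constraints,
    default_grid,
    grid_screen,
    value_frequencies,
)
from heatshock.screen import FREE_PARAMETERS, ScreenResult

TABLE_VALUES = {name: getattr(DEFAULT_PARAMS, name) for name in FREE_PARAMETERS}


def single_point_grid(**overrides):
    values = {k: [v] for k, v in TABLE_VALUES.items()}
    for k, v in overrides.items():
        values[k] = v
    return ParameterGrid(values=values)


class TestConstraintSpec:
    def test_threshold_ranges_enforced(self):
        with pytest.raises(ValueError):
            ConstraintSpec(dissoc_threshold=0.0)
        with pytest.raises(ValueError):
            ConstraintSpec(reassoc_threshold=1.5)
        with pytest.raises(ValueError):
            ConstraintSpec(basal_bound_min=1.5)


class TestCheckConstraints:
    def test_published_set_passes_all_three(self):
        rec = check_constraints(DEFAULT_PARAMS)
        assert rec["basal_bound"] and rec["dissociates"] and rec["reassociates"]
        assert rec["passed"] and rec["error"] == ""

    def test_no_titration_fails_dissociation(self):
        p = KineticParameters(k3=0.0, allow_unequal_on_rates=True)
        rec = check_constraints(p)
        assert not rec["dissociates"]
        assert not rec["passed"]

    def test_vacuous_thresholds_pass_kinetic_constraints(self):
        spec = ConstraintSpec(dissoc_threshold=1.0, reassoc_threshold=0.0,
                              basal_bound_min=0.0)
        for p in (DEFAULT_PARAMS,
                  KineticParameters(k2=0.1),
                  KineticParameters(k4=1.0)):
            rec = check_constraints(p, spec)
            assert rec["dissociates"] and rec["reassociates"]


class TestGridScreen:
    def test_published_single_combination_succeeds(self):
        res = grid_screen(single_point_grid())
        assert res.total == 1
        assert res.success_count == 1

    def test_dead_titration_branch_counted_failed(self):
        # adding k1=k3=0-like branch: an extra tiny on-rate value fails
        res = grid_screen(single_point_grid(k1=[1e-4, TABLE_VALUES["k1"]]))
        assert res.total == 2
        assert res.success_count == 1
        freq = res.frequencies()
        k1_rows = freq[freq.parameter == "k1"].set_index("value")["frequency_pct"]
        assert k1_rows[TABLE_VALUES["k1"]] == 100.0
        assert k1_rows[1e-4] == 0.0

    def test_success_count_bounded_by_total(self):
        res = grid_screen(single_point_grid(k2=[0.1, 2.783], beta=[0.01, 1.778]))
        assert 0 <= res.success_count <= res.total == 4

    def test_enumeration_order_invariant(self):
        g1 = single_point_grid(k2=[0.5, 2.783])
        g2 = single_point_grid(k2=[2.783, 0.5])
        r1 = grid_screen(g1).records.sort_values("k2").reset_index(drop=True)
        r2 = grid_screen(g2).records.sort_values("k2").reset_index(drop=True)
        pd.testing.assert_frame_equal(r1, r2)

    def test_tightening_thresholds_shrinks_success_set(self):
        grid = single_point_grid(k2=[0.2783, 2.783, 27.83],
                                 k4=[0.00464, 0.0464, 0.464])
        loose = grid_screen(grid, ConstraintSpec(dissoc_threshold=0.2,
                                                 reassoc_threshold=0.8))
        tight = grid_screen(grid, ConstraintSpec(dissoc_threshold=0.05,
                                                 reassoc_threshold=0.95))
        assert tight.success_count <= loose.success_count
        # tightened survivors are a subset of the loose survivors
        key = list(FREE_PARAMETERS)
        loose_keys = set(map(tuple, loose.successful()[key].to_numpy()))
        tight_keys = set(map(tuple, tight.successful()[key].to_numpy()))
        assert tight_keys <= loose_keys

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(values={k: [] for k in FREE_PARAMETERS})

    def test_integration_failure_recorded_not_raised(self):
        # absurd stiff corner: gigantic on-rate with huge beta
        res = grid_screen(single_point_grid(k1=[1e12], beta=[1e9]))
        assert res.total == 1  # no exception escaped; flags present
        assert set(res.records.columns) >= {"basal_bound", "dissociates",
                                            "reassociates", "passed", "error"}


class TestValueFrequencies:
    def test_single_success_gives_100_percent(self):
        res = grid_screen(single_point_grid())
        freq = value_frequencies(res)
        assert (freq.frequency_pct == 100.0).all()
        assert not freq.undefined.any()

    def test_shared_value_splits_frequencies(self):
        # fabricate records directly: two successes sharing k2, differing Kd
        rows = []
        for kd in (0.001, 0.01):
            rec = dict(TABLE_VALUES, Kd=kd, basal_bound=True, dissociates=True,
                       reassociates=True, passed=True, error="")
            rows.append(rec)
        res = ScreenResult(records=pd.DataFrame(rows), spec=ConstraintSpec())
        freq = value_frequencies(res)
        k2_rows = freq[freq.parameter == "k2"]
        assert (k2_rows.frequency_pct == 100.0).all()
        kd_rows = freq[freq.parameter == "Kd"]
        assert sorted(kd_rows.frequency_pct) == [50.0, 50.0]

    def test_zero_successes_flagged_undefined(self):
        res = grid_screen(single_point_grid(beta=[1e-6]))
        assert res.success_count == 0
        freq = value_frequencies(res)
        assert freq.undefined.all()
        assert freq.frequency_pct.isna().all()

    def test_frequencies_sum_to_100_per_parameter(self):
        res = grid_screen(single_point_grid(k2=[0.2783, 2.783],
                                            Kd=[0.0022, 0.022]))
        if res.success_count:
            freq = res.frequencies()
            sums = freq.groupby("parameter")["frequency_pct"].sum()
            assert np.allclose(sums, 100.0)


class TestDefaultGrid:
    def test_published_values_exactly_on_grid(self):
        g = default_grid(5)
        for name, center in TABLE_VALUES.items():
            assert center in g.values[name]
        assert g.size == 5 ** 6

    def test_log_spacing(self):
        g = default_grid(5, decades=2.0)
        ratios = np.diff(np.log10(g.values["k2"]))
        assert np.allclose(ratios, 1.0)
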