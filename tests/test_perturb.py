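"""Decoy titration, overexpression dose response, phosphorylation gain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatshock import (
    DEFAULT_INITIAL,
    DEFAULT_PARAMS,
    DecoyState,
    PhosphoGain,
    Protocol,
    decoy_derivatives,
    derivatives,
    dose_response,
    phospho_gain_at,
    simulate,
    simulate_decoy,
    simulate_phospho,
)
from heatshock.model import StateError

conc = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestDecoyDerivatives:
    def test_reduces_to_base_model_without_decoy(self):
        ds = DecoyState.from_base(DEFAULT_INITIAL)
        d8 = decoy_derivatives(ds, DEFAULT_PARAMS)
        d6 = derivatives(DEFAULT_INITIAL, DEFAULT_PARAMS)
        assert np.array_equal(d8[:6], d6)
        assert d8[6] == d8[7] == 0.0

    @given(hsp=conc, dec=conc, c_dec=conc, up=conc)
    def test_decoy_total_conserved(self, hsp, dec, c_dec, up):
        ds = DecoyState(hsp_free=hsp, up_free=up, decoy_free=dec, hsp_decoy=c_dec)
        d = decoy_derivatives(ds, DEFAULT_PARAMS)
        assert d[6] + d[7] == pytest.approx(0.0, abs=1e-12)

    @given(hsp=conc, dec=conc)
    def test_hsf1_still_conserved_with_decoy(self, hsp, dec):
        ds = DecoyState(hsp_free=hsp, hsf1_free=0.001, decoy_free=dec)
        d = decoy_derivatives(ds, DEFAULT_PARAMS)
        assert d[1] + d[3] == pytest.approx(0.0, abs=1e-12)

    def test_negative_state_rejected(self):
        y = DecoyState.from_base(DEFAULT_INITIAL).as_array()
        y[6] = -1e-3
        with pytest.raises(StateError):
            decoy_derivatives(y, DEFAULT_PARAMS)


class TestDecoySimulation:
    def test_decoy_titrates_hsp70_and_activates_reporter(self):
        prot = Protocol(target_temp=25.0, duration=120.0)
        base = simulate_decoy(DEFAULT_PARAMS, DecoyState.from_base(DEFAULT_INITIAL), prot)
        with_decoy = simulate_decoy(
            DEFAULT_PARAMS, DecoyState.from_base(DEFAULT_INITIAL, decoy_free=1.0), prot
        )
        assert with_decoy.species("yfp")[-1] > base.species("yfp")[-1]

    def test_decoy_depletes_free_hsp70_early(self):
        """Before feedback compensates, added decoy lowers free Hsp70."""
        times = (0.0, 0.25, 0.5, 1.0)
        prot = Protocol(target_temp=25.0, duration=1.0, output_times=times)
        base = simulate_decoy(DEFAULT_PARAMS, DecoyState.from_base(DEFAULT_INITIAL), prot)
        dec = simulate_decoy(
            DEFAULT_PARAMS, DecoyState.from_base(DEFAULT_INITIAL, decoy_free=1.0), prot
        )
        assert np.all(dec.species("hsp_free")[1:] < base.species("hsp_free")[1:])

    def test_matches_six_species_model_when_decoy_absent(self):
        prot = Protocol(duration=30.0)
        init = DEFAULT_INITIAL.replace(up_free=10.51)
        d8 = simulate_decoy(DEFAULT_PARAMS, DecoyState.from_base(init), prot)
        d6 = simulate(DEFAULT_PARAMS, init, prot)
        assert np.allclose(d8.states[:, :6], d6.states, rtol=1e-4, atol=1e-8)


@pytest.fixture(scope="module")
def curves():
    levels = [0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0]
    fl = dose_response("full_length_hsf1", levels, DEFAULT_PARAMS)
    dc = dose_response("decoy", levels, DEFAULT_PARAMS)
    return fl, dc


@pytest.fixture(scope="module")
def phospho_runs(init39):
    prot = Protocol(duration=120.0)
    gain = PhosphoGain()
    wt = simulate_phospho(DEFAULT_PARAMS, gain, prot, init=init39)
    dpo4 = simulate_phospho(DEFAULT_PARAMS, gain.constant(), prot, init=init39)
    base = simulate(DEFAULT_PARAMS, init39, prot)
    return wt, dpo4, base


class TestDoseResponse:
    def test_null_dose_matches_unperturbed_run(self, curves):
        fl, dc = curves
        prot = Protocol(target_temp=25.0, duration=120.0)
        base = simulate(DEFAULT_PARAMS, DEFAULT_INITIAL, prot)
        expected = base.species("yfp")[-1]
        assert fl.final_yfp[0] == pytest.approx(expected, rel=1e-5)
        assert dc.final_yfp[0] == pytest.approx(expected, rel=1e-5)

    def test_both_curves_monotone_non_decreasing(self, curves):
        fl, dc = curves
        assert np.all(np.diff(fl.final_yfp) >= -1e-9)
        assert np.all(np.diff(dc.final_yfp) >= -1e-9)

    def test_full_length_at_least_as_potent_as_decoy(self, curves):
        """Full-length Hsf1 both titrates Hsp70 and drives transcription,
        so its reporter output dominates the decoy's at every dose."""
        fl, dc = curves
        assert np.all(fl.final_yfp.to_numpy() >= dc.final_yfp.to_numpy() - 1e-9)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            dose_response("mkate", [0.0], DEFAULT_PARAMS)

    def test_decreasing_levels_rejected(self):
        with pytest.raises(ValueError):
            dose_response("decoy", [1.0, 0.5], DEFAULT_PARAMS)


class TestPhosphoGain:
    def test_midpoint_is_mean_of_asymptotes(self):
        g = PhosphoGain(beta_initial=1.0, beta_final=3.0, midpoint_time=20.0)
        assert phospho_gain_at(20.0, g) == pytest.approx(2.0)

    def test_left_asymptote(self):
        g = PhosphoGain(beta_initial=1.0, beta_final=3.0, midpoint_time=30.0,
                        steepness=0.5)
        assert phospho_gain_at(0.0, g) == pytest.approx(1.0, rel=0.01)

    def test_right_asymptote(self):
        g = PhosphoGain(beta_initial=1.0, beta_final=3.0, midpoint_time=20.0,
                        steepness=0.3)
        assert phospho_gain_at(500.0, g) == pytest.approx(3.0, rel=0.01)

    @given(t1=st.floats(min_value=0, max_value=200),
           dt=st.floats(min_value=0.01, max_value=100))
    def test_monotone_when_gain_positive(self, t1, dt):
        g = PhosphoGain()
        assert phospho_gain_at(t1 + dt, g) >= phospho_gain_at(t1, g)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            PhosphoGain(beta_initial=0.0)
        with pytest.raises(ValueError):
            PhosphoGain(steepness=-1.0)


class TestPhosphoSimulation:
    def test_constant_gain_reproduces_base_model(self, phospho_runs):
        _, dpo4, base = phospho_runs
        assert np.allclose(dpo4.states, base.states, rtol=1e-4, atol=1e-8)

    def test_wild_type_sustains_more_reporter_than_phospho_dead(self, phospho_runs):
        wt, dpo4, _ = phospho_runs
        assert wt.species("yfp")[-1] > dpo4.species("yfp")[-1]

    def test_reporter_advantage_starts_at_zero_and_never_shrinks(self, phospho_runs):
        wt, dpo4, _ = phospho_runs
        diff = wt.species("yfp") - dpo4.species("yfp")
        assert diff[0] == 0.0
        assert np.all(np.diff(diff) >= -1e-9)
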