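"""Gating models: Hill and concerted two-sensor curves, fits, workflows."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from permeon import (
    KCSA_GATING,
    HillParams,
    MWCParams,
    NoCrossingError,
    PoDataset,
    PoSyntheticConfig,
    fit_hill,
    fit_mwc,
    generate_po_dataset,
    hill_po,
    hill_summary_of_mwc,
    mwc_po,
    two_stage_mwc_fit,
)

from .oracles import mwc_po_highprec

CONTROL = KCSA_GATING["control"]["mwc"]
L40A = KCSA_GATING["L40A"]["mwc"]
H25R = KCSA_GATING["H25R"]["mwc"]
GRID = np.arange(4.0, 6.5 + 1e-9, 0.05)


class TestHill:
    def test_midpoint_is_half_pomax(self):
        p = HillParams(pomax=1.0, ph_half=5.3, nh=4.4)
        assert hill_po(p, 5.3) == pytest.approx(0.5)

    def test_limits(self):
        p = HillParams(pomax=0.8, ph_half=5.0, nh=3.0)
        assert hill_po(p, -20.0) == pytest.approx(0.8)
        assert hill_po(p, 30.0) == pytest.approx(0.0, abs=1e-30)

    def test_validation(self):
        with pytest.raises(ValueError):
            HillParams(pomax=0.0, ph_half=5.0, nh=2.0)
        with pytest.raises(ValueError):
            HillParams(pomax=0.5, ph_half=5.0, nh=-1.0)

    @given(
        pomax=st.floats(0.05, 1.0),
        ph_half=st.floats(3.0, 8.0),
        nh=st.floats(0.2, 8.0),
    )
    def test_monotone_and_midpoint_property(self, pomax, ph_half, nh):
        p = HillParams(pomax=pomax, ph_half=ph_half, nh=nh)
        po = hill_po(p, np.linspace(0.0, 14.0, 200))
        assert np.all(np.diff(po) <= 1e-15)
        assert hill_po(p, ph_half) == pytest.approx(pomax / 2.0, rel=1e-12)


class TestMWC:
    def test_deprotonated_limit_is_intrinsic_equilibrium(self):
        for lo in (2.5e-12, 6.2e-4, 1.3):
            p = MWCParams(lo=lo, pka1_closed=4.8, pka1_open=7.6)
            assert mwc_po(p, 30.0) == pytest.approx(lo / (1.0 + lo), rel=1e-12)
            # at the top of the physiological scale the curve is already
            # within a part in 10^3 of the limit
            assert mwc_po(p, 14.0) == pytest.approx(lo / (1.0 + lo), rel=1e-3)

    def test_state_independent_sensors_are_flat(self):
        p = MWCParams(lo=0.3, pka1_closed=6.0, pka1_open=6.0,
                      pka2_closed=5.0, pka2_open=5.0)
        po = mwc_po(p, np.linspace(0.0, 14.0, 50))
        assert np.allclose(po, 0.3 / 1.3, rtol=1e-12)

    def test_control_row_value_at_ph_5_3(self):
        # frozen from the high-precision oracle evaluation
        assert mwc_po(CONTROL, 5.3) == pytest.approx(0.6291462317, rel=1e-9)

    def test_full_protonation_limit_opens_channel(self):
        # the saturated equilibrium is Lo * 10^(4 sum dpKa) = 2.5e4, so the
        # fully protonated channel is open all but ~4e-5 of the time
        assert mwc_po(CONTROL, -10.0) == pytest.approx(1.0, abs=1e-4)
        assert mwc_po(CONTROL, -10.0) < 1.0

    def test_sensors_exchangeable(self):
        a = MWCParams(lo=1e-6, pka1_closed=4.8, pka1_open=7.6,
                      pka2_closed=5.0, pka2_open=6.2)
        b = MWCParams(lo=1e-6, pka1_closed=5.0, pka1_open=6.2,
                      pka2_closed=4.8, pka2_open=7.6)
        ph = np.linspace(0.0, 14.0, 300)
        assert np.allclose(mwc_po(a, ph), mwc_po(b, ph), rtol=1e-14)

    def test_validation(self):
        with pytest.raises(ValueError):
            MWCParams(lo=-1.0)
        with pytest.raises(ValueError):
            MWCParams(lo=1.0, pka1_closed=5.0)  # half a sensor

    @given(
        log_lo=st.floats(-15.0, 3.0),
        ph=st.floats(0.0, 14.0),
        pka1c=st.floats(2.0, 9.0),
        d1=st.floats(0.0, 5.0),
        pka2c=st.floats(2.0, 9.0),
        d2=st.floats(0.0, 5.0),
    )
    def test_log_domain_matches_high_precision(self, log_lo, ph, pka1c, d1,
                                               pka2c, d2):
        lo = 10.0 ** log_lo
        p = MWCParams(lo=lo, pka1_closed=pka1c, pka1_open=pka1c + d1,
                      pka2_closed=pka2c, pka2_open=pka2c + d2)
        ref = mwc_po_highprec(lo, ph, pka1=(pka1c, pka1c + d1),
                              pka2=(pka2c, pka2c + d2))
        assert mwc_po(p, ph) == pytest.approx(ref, rel=1e-12, abs=1e-300)

    @given(
        log_lo=st.floats(-14.0, 1.0),
        pka1c=st.floats(3.0, 8.0),
        d1=st.floats(0.0, 4.0),
        pka2c=st.floats(3.0, 8.0),
        d2=st.floats(0.0, 4.0),
    )
    def test_monotone_non_increasing_in_ph(self, log_lo, pka1c, d1, pka2c, d2):
        p = MWCParams(lo=10.0 ** log_lo, pka1_closed=pka1c,
                      pka1_open=pka1c + d1, pka2_closed=pka2c,
                      pka2_open=pka2c + d2)
        po = mwc_po(p, np.linspace(0.0, 14.0, 400))
        assert np.all(np.diff(po) <= 1e-12)


class TestSyntheticDatasets:
    def test_zero_noise_reproduces_curve(self):
        cfg = PoSyntheticConfig(params=CONTROL, noise_sd=0.0, seed=1)
        data = generate_po_dataset(cfg)
        assert np.allclose(data.po, mwc_po(CONTROL, data.ph))
        assert np.all(data.sem < 1e-12)
        assert np.all(data.n == 5)

    def test_large_replicate_count_converges_to_curve(self):
        # law of large numbers at mid-curve pH points (no clipping there)
        cfg = PoSyntheticConfig(params=L40A, ph_values=(5.0, 5.2, 5.4),
                                replicates=10_000, noise_sd=0.05, seed=2)
        data = generate_po_dataset(cfg)
        truth = mwc_po(L40A, data.ph)
        se = 0.05 / np.sqrt(10_000)
        assert np.all(np.abs(data.po - truth) < 3 * se)
        assert np.all(data.sem < 0.06 / np.sqrt(10_000) * 1.2)

    def test_saturating_lo_gives_unit_po(self):
        cfg = PoSyntheticConfig(
            params=MWCParams(lo=1e12, pka1_closed=4.8, pka1_open=7.6),
            noise_sd=0.0, seed=3,
        )
        data = generate_po_dataset(cfg)
        assert np.allclose(data.po, 1.0, atol=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PoSyntheticConfig(params=CONTROL, ph_values=(15.0,))
        with pytest.raises(ValueError):
            PoSyntheticConfig(params=CONTROL, replicates=0)
        with pytest.raises(ValueError):
            PoSyntheticConfig(params=CONTROL, noise_sd=-0.1)

    def test_seed_reproducibility(self):
        a = generate_po_dataset(PoSyntheticConfig(params=CONTROL, seed=7))
        b = generate_po_dataset(PoSyntheticConfig(params=CONTROL, seed=7))
        assert np.array_equal(a.po, b.po)

    def test_dataset_validation(self):
        with pytest.raises(ValueError, match="unique"):
            PoDataset(ph=[5.0, 5.0], po=[0.5, 0.4], sem=[0, 0], n=[1, 1])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            PoDataset(ph=[5.0], po=[1.4], sem=[0.0], n=[1])


class TestFitHill:
    def test_noiseless_self_consistency(self):
        truth = HillParams(pomax=0.93, ph_half=5.25, nh=3.1)
        data = PoDataset.from_curve(truth, GRID)
        res = fit_hill(data)
        assert res.converged
        assert res.ssr < 1e-10
        assert res.params["ph_half"] == pytest.approx(5.25, abs=1e-5)
        assert res.params["nh"] == pytest.approx(3.1, abs=1e-4)

    def test_fixed_parameter_is_pinned_and_unreported(self):
        truth = HillParams(pomax=1.0, ph_half=5.0, nh=2.0)
        data = PoDataset.from_curve(truth, GRID)
        res = fit_hill(data, fixed={"pomax": 1.0})
        assert res.params["pomax"] == 1.0
        assert res.stderr["pomax"] is None
        assert "pomax" in res.fixed

    def test_degenerate_data_flagged(self):
        data = PoDataset(ph=[4.0, 5.0, 6.0], po=[0.4, 0.4, 0.4],
                         sem=[0, 0, 0], n=[1, 1, 1])
        res = fit_hill(data)
        assert any("degenerate" in w for w in res.warnings)

    def test_l40a_concerted_curve_summarized_by_shallow_hill(self):
        data = PoDataset.from_curve(L40A, GRID)
        res = fit_hill(data)
        assert res.params["ph_half"] == pytest.approx(5.2, abs=0.1)
        assert res.params["nh"] == pytest.approx(2.0, abs=0.3)

    def test_too_few_points_rejected(self):
        data = PoDataset(ph=[5.0, 5.5], po=[0.6, 0.4], sem=[0, 0], n=[1, 1])
        with pytest.raises(ValueError, match="free parameters"):
            fit_hill(data)


class TestFitMWC:
    def test_single_free_lo_recovered_to_four_figures(self):
        data = PoDataset.from_curve(L40A, GRID)
        init = L40A.replace(lo=1e-5)
        res = fit_mwc(data, init, free=("lo",))
        assert res.converged
        assert res.params["lo"] == pytest.approx(6.2e-4, rel=1e-4)
        assert res.stderr["lo"] is not None
        assert res.stderr["pka2_open"] is None

    def test_state_collapsed_sensor_drives_bound_active(self):
        # truth has pKa1_closed = pKa1_open: stage 1 pushes the bound
        data = PoDataset.from_curve(L40A, GRID)
        init = CONTROL.replace(lo=1e-6)
        res = fit_mwc(data, init, free=("lo", "pka1_closed"))
        assert any("pka1_closed" in b for b in res.active_bounds)

    def test_two_stage_workflow_recovers_lo(self):
        data = PoDataset.from_curve(L40A, GRID)
        stage1, stage2 = two_stage_mwc_fit(data, CONTROL.replace(lo=1e-6))
        assert stage1.active_bounds
        assert stage2 is not None
        assert stage2.nfree == 1
        assert stage2.params["lo"] == pytest.approx(6.2e-4, rel=1e-3)
        assert stage2.params["pka1_closed"] == stage2.params["pka1_open"]

    def test_inactive_bound_skips_stage_two(self):
        data = PoDataset.from_curve(CONTROL, GRID)
        stage1, stage2 = two_stage_mwc_fit(data, CONTROL.replace(lo=1e-10))
        assert stage2 is None
        assert not stage1.active_bounds

    def test_one_sensor_lo_recovery_within_errors(self):
        cfg = PoSyntheticConfig(params=H25R, seed=11)
        data = generate_po_dataset(cfg)
        res = fit_mwc(data, H25R.replace(lo=1e-2), free=("lo",))
        assert res.converged
        se = res.stderr["log10_lo"]
        assert se is not None
        assert abs(res.params["log10_lo"] - np.log10(7e-4)) < 3 * se

    def test_absent_sensor_cannot_be_freed(self):
        data = PoDataset.from_curve(H25R, GRID)
        with pytest.raises(ValueError, match="sensor absent"):
            fit_mwc(data, H25R, free=("lo", "pka1_closed"))


class TestHillSummary:
    def test_flat_curve_raises(self):
        flat = MWCParams(lo=0.4, pka1_closed=6.0, pka1_open=6.0)
        with pytest.raises(NoCrossingError):
            hill_summary_of_mwc(flat)

    def test_deterministic(self):
        a = hill_summary_of_mwc(CONTROL)
        b = hill_summary_of_mwc(CONTROL)
        assert (a.pomax, a.ph_half, a.nh) == (b.pomax, b.ph_half, b.nh)

    def test_control_and_e118a_midpoints(self):
        assert hill_summary_of_mwc(CONTROL).ph_half == pytest.approx(5.3, abs=0.1)
        e118a = KCSA_GATING["E118A"]["mwc"]
        assert hill_summary_of_mwc(e118a).ph_half == pytest.approx(5.5, abs=0.1)

    def test_midpoint_matches_curve_crossing(self):
        # the fitted pH_half sits where the concerted curve crosses Pomax/2
        hill = hill_summary_of_mwc(H25R)
        po_at_half = mwc_po(H25R, hill.ph_half)
        assert po_at_half == pytest.approx(hill.pomax / 2.0, abs=0.02)
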