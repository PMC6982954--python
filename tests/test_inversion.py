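"""Mixture rule, time-constant relations, and the full inversion chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmcal import (mixture_rho_cp, invert_mixture, tau_from_rho_cp,
                   rho_cp_from_tau, sample_time_constant,
                   HeatCapacityModel, estimate_heat_capacity,
                   fit_exponential, generate_trace, SyntheticSpec,
                   reference_profile, DomainError, SampleSpec, YEAST)
from dataclasses import replace

UM = 1e-6


class TestMixtureRule:
    def test_equal_components_identity(self):
        assert mixture_rho_cp(2e6, 2e6, 34.0, 1.0) == pytest.approx(2e6)

    def test_volume_weighted_value(self):
        # (1.9e6*34 + 5.4e6*1)/35
        got = mixture_rho_cp(1.9e6, 5.4e6, 34.0, 1.0)
        assert got == pytest.approx((1.9e6 * 34 + 5.4e6) / 35.0)
        assert got == pytest.approx(2.0e6, rel=1e-3)

    def test_vanishing_sample_limit(self):
        assert mixture_rho_cp(1.9e6, 5.4e6, 1.0, 1e-12) == \
            pytest.approx(1.9e6, rel=1e-9)

    @given(b=st.floats(1e5, 1e7), s=st.floats(1e5, 1e7),
           r=st.floats(0.1, 1000.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_invert_is_exact_inverse(self, b, s, r):
        total = mixture_rho_cp(b, s, r, 1.0)
        back, _ = invert_mixture(total, b, r, 1.0)
        assert back == pytest.approx(s, rel=1e-10)

    def test_hand_value_inverse(self):
        got, notes = invert_mixture(2.0e6, 1.9e6, 34.0, 1.0)
        assert got == pytest.approx(2.0e6 * 35 - 1.9e6 * 34, rel=1e-12)
        assert got == pytest.approx(5.4e6, rel=1e-12)

    def test_cancellation_warning_fires(self):
        # total barely above the beam-only baseline
        _, notes = invert_mixture(1.901e6, 1.9e6, 34.0, 1.0)
        assert any("ill-conditioned" in n for n in notes)

    def test_nonpositive_result_flagged(self):
        got, notes = invert_mixture(1.8e6, 1.9e6, 34.0, 1.0)
        assert got < 0
        assert any("non-positive" in n for n in notes)


class TestTimeConstantRelations:
    def test_reported_tau_to_rho_cp(self):
        # tau = 230 ms, h = 20, Lc = 1.1 um
        got = rho_cp_from_tau(0.230, 1.1 * UM, 20.0)
        assert got == pytest.approx(0.230 * 20.0 / 1.1e-6)
        assert got == pytest.approx(4.18e6, rel=1e-3)

    @given(rho_cp=st.floats(1e5, 1e7), lc=st.floats(1e-7, 1e-5),
           h=st.floats(1.0, 100.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_mutually_inverse(self, rho_cp, lc, h):
        tau = tau_from_rho_cp(rho_cp, lc, h)
        assert rho_cp_from_tau(tau, lc, h) == pytest.approx(rho_cp,
                                                            rel=1e-12)

    def test_tau_proportional_to_lc(self):
        assert tau_from_rho_cp(2e6, 2e-6, 20.0) == \
            pytest.approx(2 * tau_from_rho_cp(2e6, 1e-6, 20.0))

    def test_zero_h_rejected(self):
        with pytest.raises(DomainError):
            tau_from_rho_cp(2e6, 1e-6, 0.0)


class TestSampleTimeConstant:
    def test_reported_inputs_give_181_ms(self):
        """The chain evaluated at the reported fitted time constants gives
        ~181 ms — not the reported 230 ms (a documented discrepancy)."""
        tau_s, notes = sample_time_constant(66.5e-3, 69.3e-3, 1.0 * UM,
                                            1.1 * UM, 34.0)
        assert tau_s == pytest.approx(1.1 * (69.3e-3 + 34 * 2.8e-3),
                                      rel=1e-12)
        assert tau_s * 1e3 == pytest.approx(180.95, abs=0.01)
        assert not notes

    def test_equal_time_constants(self):
        tau_s, _ = sample_time_constant(50e-3, 50e-3, 1.0 * UM, 1.1 * UM,
                                        34.0)
        assert tau_s == pytest.approx(1.1 * 50e-3, rel=1e-12)

    def test_negative_result_flagged(self):
        tau_s, notes = sample_time_constant(70e-3, 60e-3, 1e-6, 1.1e-6,
                                            34.0)
        assert tau_s < 0
        assert notes

    @given(tau_b=st.floats(1e-3, 1.0), dtau=st.floats(1e-5, 0.5),
           r=st.floats(0.5, 200.0), lcr=st.floats(0.2, 5.0),
           h=st.floats(1.0, 100.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_chain_equivalence(self, tau_b, dtau, r, lcr, h):
        """Inverting the mixture rule in heat-capacity units and the
        direct time-constant chain are the same algebra."""
        tau_t = tau_b + dtau
        lc_b = 1e-6
        lc_s = lcr * lc_b
        direct, _ = sample_time_constant(tau_b, tau_t, lc_b, lc_s, r)
        rho_cp_s, _ = invert_mixture(rho_cp_from_tau(tau_t, lc_b, h),
                                     rho_cp_from_tau(tau_b, lc_b, h),
                                     r, 1.0)
        via_mixture = rho_cp_s * lc_s / h
        assert direct == pytest.approx(via_mixture, rel=1e-10)


class TestEstimateHeatCapacity:
    @pytest.fixture
    def fits(self, ref_model):
        tr_b = generate_trace(SyntheticSpec(model=ref_model.without_sample()))
        tr_t = generate_trace(SyntheticSpec(model=ref_model))
        return fit_exponential(tr_b), fit_exponential(tr_t)

    def test_noiseless_roundtrip_recovers_truth(self, ref_model, fits):
        est = HeatCapacityModel(*fits, ref_model).fit(density=1100.0)
        truth = YEAST.volumetric_heat_capacity
        assert est.valid
        assert est.rho_cp_S == pytest.approx(truth, rel=1e-6)
        assert est.cp_S == pytest.approx(2170.0, rel=1e-6)
        assert est.method_tag == "tau_chain"

    def test_both_methods_agree(self, ref_model, fits):
        a = HeatCapacityModel(*fits, ref_model).fit(method="tau_chain")
        b = HeatCapacityModel(*fits, ref_model).fit(
            method="mixture_inverse")
        assert a.rho_cp_S == pytest.approx(b.rho_cp_S, rel=1e-12)

    def test_summary_mentions_conditioning(self, ref_model, fits):
        est = HeatCapacityModel(*fits, ref_model).fit()
        # V_B/V_S = 34 makes the subtraction ill-conditioned by design
        assert any("ill-conditioned" in f for f in est.flags)
        assert "tau_S" in est.summary()

    def test_density_needed_for_specific_heat(self, ref_model, fits):
        est = HeatCapacityModel(*fits, ref_model).fit()
        assert est.cp_S is None
        with pytest.raises(DomainError):
            HeatCapacityModel(*fits, ref_model).fit(density=-1.0)

    def test_needs_sample(self, ref_model, fits):
        with pytest.raises(DomainError):
            HeatCapacityModel(*fits, ref_model.without_sample())

    def test_se_grows_with_volume_ratio(self, ref_model, fits):
        """At fixed fit noise the standard error scales with V_B/V_S —
        the cancellation caveat made quantitative."""
        ses = []
        for r in (5.0, 34.0, 100.0):
            m = replace(ref_model, volume_ratio_override=r)
            ses.append(HeatCapacityModel(*fits, m).fit().se_rho_cp_S)
        assert ses[0] < ses[1] < ses[2]
        # asymptotically proportional to the ratio
        assert ses[2] / ses[1] == pytest.approx(100.0 / 34.0, rel=0.1)

    def test_position_independence_lumped(self, ref_model, fits):
        """In the lumped model the sample's position along the beam is
        irrelevant: only its added heat capacity enters."""
        moved = replace(ref_model,
                        sample=replace(ref_model.sample,
                                       position_on_beam=450 * UM))
        a = HeatCapacityModel(*fits, ref_model).fit()
        tr_t2 = generate_trace(SyntheticSpec(model=moved))
        fit_t2 = fit_exponential(tr_t2)
        b = HeatCapacityModel(fits[0], fit_t2, moved).fit()
        assert b.tau_T == pytest.approx(a.tau_T, rel=1e-9)
        assert b.rho_cp_S == pytest.approx(a.rho_cp_S, rel=1e-6)

    def test_position_independence_distributed(self, ref_model):
        """Moving the sample from mid-beam toward the tip leaves the
        fitted loaded time constant essentially unchanged (the beam is
        spatially isothermal)."""
        taus = []
        for pos in (300 * UM, 450 * UM):
            m = replace(ref_model,
                        sample=replace(ref_model.sample,
                                       position_on_beam=pos))
            tr = generate_trace(SyntheticSpec(model=m, n_points=80,
                                              t_end=0.5,
                                              thermal_model="distributed"))
            taus.append(fit_exponential(tr).tau)
        assert taus[1] == pytest.approx(taus[0], rel=5e-3)

    def test_nonconverged_fit_flagged(self, ref_model, fits):
        import dataclasses
        bad = dataclasses.replace(fits[1], converged=False)
        est = HeatCapacityModel(fits[0], bad, ref_model).fit()
        assert not est.valid
        assert any("converge" in f for f in est.flags)
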