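"""Lumped and distributed transient thermal models."""

import numpy as np
import pytest

from bmcal import (BeamModel, BeamGeometry, LayerStack, Material,
                   Environment, Irradiation, DomainError,
                   lumped_params, lumped_temperature_analytic,
                   simulate_lumped_ode, simulate_distributed_1d,
                   spatial_uniformity_metric, ExponentialDecayModel)
from bmcal.thermal import ThermalTrace

UM = 1e-6


def single_layer_model(rho_cp=1.39e6, t=1 * UM, h=20.0, q=500.0,
                       sides="one", **irr_kw):
    mat = Material("m", rho_cp / 1000.0, 1000.0, 10.0, 1e-6, 1e9)
    stack = LayerStack(mat, mat, t / 2, t / 2)
    geom = BeamGeometry(600 * UM, 76 * UM, stack)
    return BeamModel(geometry=geom,
                     environment=Environment(h_conv=h,
                                             convection_sides=sides),
                     irradiation=Irradiation(absorbed_flux=q, **irr_kw))


class TestLumpedParams:
    def test_time_constant_and_steady_rise(self):
        # C'' = 1.39 J/(m^2 K), h_eff = 20 -> tc = 69.5 ms, rise = 25 K
        p = lumped_params(single_layer_model())
        assert p.tc == pytest.approx(1.39 / 20.0)
        assert p.steady_rise == pytest.approx(500.0 / 20.0)

    def test_no_flux_steady_at_ambient(self):
        p = lumped_params(single_layer_model(q=0.0))
        assert p.T_inf == pytest.approx(293.15)

    def test_both_sides_halve_the_time_constant(self):
        one = lumped_params(single_layer_model(sides="one"))
        both = lumped_params(single_layer_model(sides="both"))
        assert both.tc == pytest.approx(one.tc / 2)
        assert both.steady_rise == pytest.approx(one.steady_rise / 2)

    def test_zero_h_flagged_infinite(self):
        p = lumped_params(single_layer_model(h=0.0))
        assert np.isinf(p.tc)
        with pytest.raises(DomainError):
            lumped_temperature_analytic(p, [0.0, 0.1])


class TestAnalyticSolution:
    def test_limits_and_efolding(self):
        p = lumped_params(single_layer_model())
        assert lumped_temperature_analytic(p, 0.0) == pytest.approx(p.T0)
        assert lumped_temperature_analytic(p, 100 * p.tc) == \
            pytest.approx(p.T_inf)
        at_tc = float(lumped_temperature_analytic(p, p.tc))
        frac = (at_tc - p.T0) / (p.T_inf - p.T0)
        assert frac == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_negative_time_rejected(self):
        p = lumped_params(single_layer_model())
        with pytest.raises(DomainError):
            lumped_temperature_analytic(p, -0.1)


class TestLumpedODE:
    def test_matches_analytic_under_constant_flux(self):
        m = single_layer_model()
        p = lumped_params(m)
        t = np.linspace(0, 0.5, 501)
        tr = simulate_lumped_ode(m, t)
        exact = lumped_temperature_analytic(p, t)
        assert np.max(np.abs(tr.temperature - exact)) < 1e-9 * p.steady_rise

    def test_zero_flux_constant_trace(self):
        m = single_layer_model(q=0.0)
        tr = simulate_lumped_ode(m, np.linspace(0, 1, 50))
        assert np.allclose(tr.temperature, 293.15, atol=1e-12)

    def test_step_off_decays_with_same_time_constant(self):
        m = single_layer_model(t_on=0.0, duration=0.6)
        p = lumped_params(m)
        t = np.linspace(0, 1.2, 1201)
        tr = simulate_lumped_ode(m, t)
        decay = t >= 0.6
        fit = ExponentialDecayModel(t[decay] - 0.6,
                                    tr.temperature[decay]).fit()
        assert fit.tau == pytest.approx(p.tc, rel=1e-6)
        assert fit.v_inf == pytest.approx(293.15, abs=1e-6)

    def test_energy_conservation(self):
        m = single_layer_model()
        t = np.linspace(0, 0.4, 4001)
        tr = simulate_lumped_ode(m, t)
        c = m.areal_heat_capacity
        h = m.h_eff
        stored = c * (tr.temperature[-1] - tr.temperature[0])
        lost = h * np.trapezoid(tr.temperature - 293.15, t)
        supplied = 500.0 * t[-1]
        assert stored + lost == pytest.approx(supplied, rel=1e-6)

    def test_monotone_bounded_approach(self):
        m = single_layer_model()
        p = lumped_params(m)
        tr = simulate_lumped_ode(m, np.linspace(0, 1, 400))
        assert np.all(np.diff(tr.temperature) >= 0)
        assert np.all(tr.temperature <= p.T_inf + 1e-12)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(DomainError):
            simulate_lumped_ode(single_layer_model(), [0.0, 0.2, 0.1])


class TestDistributed:
    def test_adiabatic_uniform_field_matches_lumped(self, ref_beam_only):
        p = lumped_params(ref_beam_only)
        t = np.linspace(0, 0.5, 101)
        tr = simulate_distributed_1d(ref_beam_only, n_nodes=50, times=t,
                                     max_step=p.tc / 500)
        exact = lumped_temperature_analytic(p, t)
        err = np.max(np.abs(tr.temperature - exact[:, None]))
        assert err < 1e-6 * p.steady_rise

    def test_zero_flux_stays_at_ambient(self, ref_beam_only):
        m = BeamModel(geometry=ref_beam_only.geometry,
                      environment=ref_beam_only.environment,
                      irradiation=Irradiation(absorbed_flux=0.0))
        tr = simulate_distributed_1d(m, n_nodes=30,
                                     times=np.linspace(0, 0.2, 21))
        assert np.allclose(tr.temperature, 293.15, atol=1e-9)

    def test_reference_profile_spatially_uniform(self, ref_beam_only):
        tr = simulate_distributed_1d(ref_beam_only, n_nodes=100,
                                     times=np.linspace(0, 0.5, 101))
        p = lumped_params(ref_beam_only)
        spread = tr.temperature[-1].max() - tr.temperature[-1].min()
        assert spread < 1e-4 * p.steady_rise
        assert spatial_uniformity_metric(tr) < 1e-4

    def test_weaker_conduction_homogenises_slower(self, ref_beam_only):
        """Relaxation of a hot-tip initial gradient: after a fixed time
        the residual spatial spread grows as the conductance shrinks."""
        m = BeamModel(geometry=ref_beam_only.geometry,
                      environment=ref_beam_only.environment,
                      irradiation=Irradiation(absorbed_flux=0.0))
        x = np.linspace(0, 1, 40)
        T0 = 293.15 + 10.0 * x  # 10 K anchor-to-tip gradient
        spreads = []
        for scale in (1.0, 1e-2, 1e-4):
            tr = simulate_distributed_1d(m, n_nodes=40,
                                         times=np.linspace(0, 0.2, 21),
                                         T0=T0, conductance_scale=scale)
            spreads.append(float(tr.temperature[-1].max()
                                 - tr.temperature[-1].min()))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_fixed_anchor_creates_persistent_gradient(self, ref_beam_only):
        tr = simulate_distributed_1d(ref_beam_only, n_nodes=40,
                                     times=np.linspace(0, 0.5, 51),
                                     anchor="fixed")
        assert spatial_uniformity_metric(tr) > 0.5

    def test_grid_refinement_converges(self, ref_beam_only):
        t = np.linspace(0, 0.3, 31)
        p = lumped_params(ref_beam_only)
        coarse = simulate_distributed_1d(ref_beam_only, n_nodes=30,
                                         times=t, anchor="fixed",
                                         max_step=2e-3)
        fine = simulate_distributed_1d(ref_beam_only, n_nodes=59,
                                       times=t, anchor="fixed",
                                       max_step=1e-3)
        # compare on the shared (coarse) nodes: node 2i of the fine grid
        diff = np.max(np.abs(fine.temperature[:, ::2]
                             - coarse.temperature))
        assert diff < 1e-3 * p.steady_rise

    def test_uniformity_metric_rejects_lumped_trace(self, ref_beam_only):
        tr = simulate_lumped_ode(ref_beam_only, np.linspace(0, 0.1, 11))
        with pytest.raises(DomainError):
            spatial_uniformity_metric(tr)

    def test_uniform_trace_metric_zero(self):
        tr = ThermalTrace(times=np.linspace(0, 1, 5),
                          temperature=np.full((5, 4), 300.0),
                          model_tag="distributed", x=np.linspace(0, 1, 4))
        assert spatial_uniformity_metric(tr) == 0.0


class TestTraceValidation:
    def test_times_must_increase(self):
        with pytest.raises(DomainError):
            ThermalTrace(times=np.array([0.0, 0.0, 1.0]),
                         temperature=np.zeros(3), model_tag="lumped")

    def test_finite_temperatures(self):
        with pytest.raises(DomainError):
            ThermalTrace(times=np.array([0.0, 1.0]),
                         temperature=np.array([1.0, np.nan]),
                         model_tag="lumped")

    def test_distributed_needs_node_grid(self):
        with pytest.raises(DomainError):
            ThermalTrace(times=np.array([0.0, 1.0]),
                         temperature=np.zeros((2, 3)),
                         model_tag="distributed", x=None)
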