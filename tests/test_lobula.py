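"""Lobula network: receptive fields, conductances, membrane dynamics, symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emdlobula import (
    IM_KERNEL,
    PREWITT_KERNEL,
    LobulaNetwork,
    LobulaState,
    NetworkConfig,
    ReceptiveField,
    activation,
    conductances,
    gaussian_rf,
    modulate_octopamine,
    step_network,
    synaptic_current,
)


class TestGaussianRF:
    def test_side_one_is_identity(self):
        assert np.array_equal(gaussian_rf(1), [[1.0]])

    def test_unit_sum_and_rotation_symmetry(self):
        k = gaussian_rf(7)
        assert abs(k.sum() - 1.0) < 1e-12
        assert np.allclose(k, np.rot90(k))

    def test_center_corner_ratio(self):
        k = gaussian_rf(7)  # SD = 7/4 = 1.75
        expected = np.exp((2 * 3**2) / (2 * 1.75**2))
        assert k[3, 3] / k[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_even_side_rejected(self):
        with pytest.raises(ValueError):
            gaussian_rf(6)


class TestConductances:
    def test_positive_input_positive_kernel(self):
        rf = ReceptiveField(gaussian_rf(5), +1)
        gp, gm = conductances(np.ones((8, 8)), rf)
        assert not gm.any() and gp.min() > 0

    def test_il_is_sign_flipped_ir(self):
        presyn = np.random.default_rng(0).random((8, 10))
        gp_r, gm_r = conductances(presyn, ReceptiveField(gaussian_rf(5), +1))
        gp_l, gm_l = conductances(presyn, ReceptiveField(gaussian_rf(5), -1))
        assert np.allclose(gp_l, -gm_r) and np.allclose(gm_l, -gp_r)

    def test_uniform_input_prewitt_silent_interior(self):
        gp, gm = conductances(np.ones((10, 10)), ReceptiveField(PREWITT_KERNEL, +1))
        assert not gp[1:-1, 1:-1].any() and not gm[1:-1, 1:-1].any()

    def test_im_kernel_matches_printed_form(self):
        assert IM_KERNEL.sum() == pytest.approx(1.0)
        assert IM_KERNEL[1, 1] == 0.6 and IM_KERNEL[0, 1] == 0.1
        assert PREWITT_KERNEL[0, 0] == 0.05 and PREWITT_KERNEL[0, 2] == -0.05


class TestSynapticCurrentAndActivation:
    def test_zero_conductance_zero_current(self):
        cfg = NetworkConfig()
        v = np.full((3, 3), -60.0)
        assert not synaptic_current(v, np.zeros((3, 3)), np.zeros((3, 3)), cfg, 150).any()

    def test_current_vanishes_at_reversal(self):
        cfg = NetworkConfig()
        v = np.full((2, 2), cfg.e_ext)
        i = synaptic_current(v, np.ones((2, 2)), np.zeros((2, 2)), cfg, 99.0)
        assert np.allclose(i, 0.0)

    def test_unit_excitation_drives_to_zero_mv(self):
        cfg = NetworkConfig()
        v = np.full((1, 1), -50.0)
        i = synaptic_current(v, np.full((1, 1), 1.0), np.zeros((1, 1)), cfg, 1.0)
        assert i[0, 0] == pytest.approx(50.0)

    def test_activation_half_point_and_rest(self):
        assert activation(np.array([-40.0]), -40.0, 0.5)[0] == pytest.approx(0.5)
        rest = activation(np.array([-50.0]), -40.0, 0.5)[0]
        assert rest == pytest.approx(2.06e-9, rel=0.01)

    def test_activation_monotone(self):
        v = np.linspace(-80, 0, 200)
        out = activation(v, -40.0, 0.5)
        assert np.all(np.diff(out) >= 0)


class TestDynamics:
    def test_rest_is_fixed_point(self):
        cfg = NetworkConfig()
        net = LobulaNetwork((6, 8), cfg)
        zero = np.zeros((6, 8))
        for _ in range(5):
            net.step_frame(zero)
        # rest is a fixed point up to the sigmoid's resting tail (~2e-9),
        # which leaks an O(1e-7 mV) drive into downstream modules
        for m, v in net.state.v.items():
            assert np.allclose(v, -50.0, atol=1e-5), m

    def test_excitatory_steady_state_minus_25(self):
        # alpha*g+ = 1, g- = 0: V_inf = (E_Leak + 1*E_ext)/(1+1) = -25 mV
        cfg = NetworkConfig(integrator="rk4")
        from emdlobula.lobula import _advance_membrane

        v = np.full((1, 1), -50.0)
        g = np.full((1, 1), 1.0)
        for _ in range(2000):
            v = _advance_membrane(v, g, np.zeros((1, 1)), cfg, 1.0, cfg.tau_m, 0.4)
        assert v[0, 0] == pytest.approx(-25.0, abs=1e-9)

    def test_exact_propagator_matches_closed_form(self):
        cfg = NetworkConfig(integrator="exact")
        from emdlobula.lobula import _advance_membrane

        v0, ag, bg = -47.0, 0.8, 0.3
        v = np.full((1, 1), v0)
        for k in range(25):
            v = _advance_membrane(v, np.full((1, 1), ag), np.full((1, 1), -bg),
                                  cfg, 1.0, cfg.tau_m, 0.4)
        denom = 1 + ag + bg
        v_inf = (-50.0 + ag * 0.0 + bg * -80.0) / denom
        expected = v_inf + (v0 - v_inf) * np.exp(-25 * 0.4 * denom / cfg.tau_m)
        assert abs(v[0, 0] - expected) / abs(expected) < 1e-12

    def test_rk4_matches_exact_at_truncation_level(self):
        from emdlobula.lobula import _advance_membrane

        v0 = np.full((1, 1), -47.0)
        g = np.full((1, 1), 1.0)
        vs = {}
        for integ in ("rk4", "exact"):
            cfg = NetworkConfig(integrator=integ)
            v = v0.copy()
            for _ in range(25):
                v = _advance_membrane(v, g, np.zeros((1, 1)), cfg, 1.0, cfg.tau_m, 0.4)
            vs[integ] = v[0, 0]
        # h = dt(1+ag)/tau = 0.16; RK4 local error ~h^5/120 per substep
        assert abs(vs["rk4"] - vs["exact"]) / abs(vs["exact"]) < 5e-5

    @given(
        hnp.arrays(np.float64, (4, 5), elements=st.floats(0, 3)),
        hnp.arrays(np.float64, (4, 5), elements=st.floats(0, 3)),
    )
    @settings(deadline=None, max_examples=25)
    def test_voltage_bounds(self, gp, gm):
        # with nonnegative conductances V stays within [E_inh, E_ext]
        from emdlobula.lobula import _advance_membrane

        cfg = NetworkConfig()
        v = np.full((4, 5), -50.0)
        for _ in range(50):
            v = _advance_membrane(v, gp, -gm, cfg, 1.0, cfg.tau_m, 0.4)
        assert np.all(v >= cfg.e_inh - 1e-9) and np.all(v <= cfg.e_ext + 1e-9)

    def test_step_network_functional_leaves_input_state(self):
        cfg = NetworkConfig()
        state = LobulaState.at_rest((4, 6), cfg)
        motion = np.zeros((4, 6))
        motion[2, 3] = 0.05
        new = step_network(motion, state, cfg)
        assert np.array_equal(state.v["Ir"], np.full((4, 6), -50.0))
        assert new.v["Ir"].max() > -50.0

    def test_shape_mismatch_rejected(self):
        net = LobulaNetwork((4, 6), NetworkConfig())
        with pytest.raises(ValueError):
            net.step_frame(np.zeros((4, 7)))


class TestMirrorSymmetry:
    def test_ir_il_swap_and_im_mirror_exact(self):
        rng = np.random.default_rng(8)
        cfg = NetworkConfig(rf_side_emd_units=5)
        motion = [rng.normal(0, 0.02, (8, 12)) for _ in range(4)]
        net_f = LobulaNetwork((8, 12), cfg)
        net_m = LobulaNetwork((8, 12), cfg)
        for mf in motion:
            net_f.step_frame(mf)
            net_m.step_frame(-mf[:, ::-1])
        # exact up to floating-point summation order inside the convolution
        assert np.allclose(net_m.state.v["Ir"], net_f.state.v["Il"][:, ::-1], atol=1e-10)
        assert np.allclose(net_m.state.v["Il"], net_f.state.v["Ir"][:, ::-1], atol=1e-10)
        assert np.allclose(net_m.state.v["Im"], net_f.state.v["Im"][:, ::-1], atol=1e-10)

    def test_edge_layer_conductance_antisymmetry(self):
        # the shared oriented Prewitt kernel flips sign under mirroring:
        # excitation of the mirrored Lr equals mirrored inhibition of Ll
        rng = np.random.default_rng(9)
        act = rng.random((8, 12))
        gp_f, gm_f = conductances(act, ReceptiveField(PREWITT_KERNEL, +1))
        gp_m, gm_m = conductances(act[:, ::-1], ReceptiveField(PREWITT_KERNEL, +1))
        assert np.allclose(gp_m, -gm_f[:, ::-1], atol=1e-15)
        assert np.allclose(gm_m, -gp_f[:, ::-1], atol=1e-15)


class TestOctopamine:
    def test_identity_when_unshifted(self):
        cfg = NetworkConfig()
        assert modulate_octopamine(cfg, -40.0) == cfg

    def test_scope_restriction(self):
        cfg = modulate_octopamine(NetworkConfig(), -28.0, scope=("Ir", "Il"))
        assert cfg.theta_of("Ir") == -28.0
        assert cfg.theta_of("Il") == -28.0
        assert cfg.theta_of("Im") == -40.0
        wider = modulate_octopamine(cfg, -26.0, scope=("Ir", "Il", "Im"))
        assert wider.theta_of("Im") == -26.0

    def test_beta_override(self):
        cfg = modulate_octopamine(NetworkConfig(), -28.0, beta_new=0.25)
        assert cfg.beta_of("Ir") == 0.25 and cfg.beta_of("Lm") == 0.5

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            modulate_octopamine(NetworkConfig(), -28.0, scope=("Ix",))


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        NetworkConfig(tau_m=0.0)
    with pytest.raises(ValueError):
        NetworkConfig(rf_side_emd_units=4)
    with pytest.raises(ValueError):
        NetworkConfig(e_inh=-40.0)  # violates E_inh < E_Leak
    with pytest.raises(ValueError):
        NetworkConfig(integrator="euler")
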