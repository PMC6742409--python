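import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexstim import (ActivationParams, FieldSource, Morphology, Structure,
                        activating_function, evaluate, make_fiber,
                        spike_probability, tangent_directions, trigger_region)
from cortexstim.activation import FStencil


def analytic_point_source_f(fiber, src, diameter=2.0, rho_i=300.0):
    """Closed-form f for a straight fiber along x under a point source.

    Phi(x) = C / sqrt((x-x0)^2 + h^2)  with h the fiber-to-source distance;
    d2Phi/dx2 = C (2 u^2 - h^2) / (u^2 + h^2)^(5/2), u = x - x0.
    """
    C = 10.0 * src.rho_e_ohm_cm * src.current_ua / (4.0 * np.pi)
    u = fiber.xyz[:, 0] - src.center[0]
    h2 = (fiber.xyz[:, 2] - src.center[2]) ** 2 \
        + (fiber.xyz[:, 1] - src.center[1]) ** 2
    phi_dd = C * (2 * u ** 2 - h2) / (u ** 2 + h2) ** 2.5
    return 1e9 * diameter / (4.0 * rho_i * 1e4) * phi_dd


class TestTangents:
    def test_straight_fiber(self):
        fib = make_fiber((0, 0, 10), (1, 0, 0), 100, 1.0)
        t = tangent_directions(fib, 10.0)
        np.testing.assert_allclose(np.abs(t[1:, 0]), 1.0, atol=1e-9)

    def test_jittered_fiber_recovers_direction(self):
        rng = np.random.default_rng(0)
        n = 101
        xyz = np.column_stack([np.arange(n, dtype=float),
                               rng.uniform(-0.5, 0.5, n),
                               np.full(n, 30.0)])
        ids = np.arange(1, n + 1)
        parents = np.concatenate([[-1], ids[:-1]])
        m = Morphology(ids, parents, xyz, np.ones(n),
                       np.full(n, int(Structure.AXON)))
        t = tangent_directions(m, 10.0)
        angles = np.degrees(np.arccos(np.clip(np.abs(t[5:-5, 0]), 0, 1)))
        assert angles.max() < 10.0

    def test_right_angle_branch_limbs(self):
        # trunk along +x, branch along +y from the midpoint
        pts = [(float(i), 0.0, 0.0) for i in range(21)]
        ids = list(range(1, 22))
        parents = [-1] + ids[:-1]
        for j in range(1, 11):
            ids.append(21 + j)
            parents.append(11 if j == 1 else 20 + j)   # branch at x=10
            pts.append((10.0, float(j), 0.0))
        m = Morphology(np.array(ids), np.array(parents), np.array(pts),
                       np.ones(len(ids)),
                       np.full(len(ids), int(Structure.AXON)))
        t = tangent_directions(m, 6.0)
        # far from the junction each limb's tangent matches its own direction
        assert abs(t[5, 0]) > 0.99
        assert abs(t[26, 1]) > 0.99


class TestActivatingFunction:
    def test_uniform_field_gives_zero(self, params):
        # a far-away point source is locally uniform: f ~ 0 at fixture scale
        src = FieldSource(kind="point", center=(0, 0, 1e7), current_ua=100.0)
        fib = make_fiber((0, 0, 50), (1, 0, 0), 100, 1.0)
        f = activating_function(fib, src, params)
        assert np.abs(f).max() < 1e-9

    def test_matches_analytic_second_derivative(self, params):
        src = FieldSource(kind="point", center=(0, 0, 0), current_ua=-80.0)
        fib = make_fiber((-150, 0, 60.0), (1, 0, 0), 300, 0.5)
        f = activating_function(fib, src, params)
        ref = analytic_point_source_f(fib, src)
        interior = slice(2, -2)
        err = np.abs(f[interior] - ref[interior]) / np.abs(ref).max()
        assert err.max() < 0.01

    def test_point_source_sign_structure(self, params):
        # anodal point source above a horizontal fiber: hyperpolarizes
        # beneath, depolarizes the flanks
        src = FieldSource(kind="point", center=(0, 0, 0), current_ua=100.0)
        fib = make_fiber((-300, 0, 60.0), (1, 0, 0), 600, 1.0)
        f = activating_function(fib, src, params)
        mid = len(fib) // 2
        assert f[mid] < 0
        assert f[20] > 0 and f[-20] > 0

    def test_plate_sign_structure_and_polarity_flip(self, anodal_plate,
                                                    params,
                                                    horizontal_fiber,
                                                    vertical_fiber):
        fh = activating_function(horizontal_fiber, anodal_plate, params)
        fv = activating_function(vertical_fiber, anodal_plate, params)
        mid_h = len(horizontal_fiber) // 2
        assert fh[mid_h] < 0                      # horizontal hyperpolarized
        assert fv[5:60].max() > 0                 # vertical depolarized on top
        cath = anodal_plate.with_current(-100.0)
        np.testing.assert_allclose(
            activating_function(horizontal_fiber, cath, params), -fh,
            rtol=1e-9)
        np.testing.assert_allclose(
            activating_function(vertical_fiber, cath, params), -fv,
            rtol=1e-9)

    def test_grid_refinement_stability(self, anodal_plate, params):
        lengths = {}
        for dx in (1.0, 0.5):
            fib = make_fiber((0, 0, 20), (0, 0, 1), 400, dx)
            res = evaluate(fib, anodal_plate, params, myelinated=True)
            lengths[dx] = res.total_triggered_length_um
        assert lengths[0.5] == pytest.approx(lengths[1.0], rel=0.05)

    def test_stencil_matches_direct_evaluation(self, anodal_plate, params,
                                               small_arbor):
        from cortexstim.morphology import resample
        m = resample(small_arbor, 2.0)
        st_ = FStencil(m, params)
        placed = m.placed((100.0, 0.0, 450.0), 0.9)
        f_direct = activating_function(placed, anodal_plate, params)
        f_fast = st_.evaluate(anodal_plate, 0.9, (100.0, 0.0, 450.0))
        assert np.abs(f_fast - f_direct).max() \
            < 0.01 * np.abs(f_direct).max()


class TestTriggerRegion:
    def test_all_below_threshold(self, params):
        fib = make_fiber((0, 0, 10), (1, 0, 0), 100, 1.0)
        res = trigger_region(np.zeros(len(fib)), fib, params, True)
        assert len(res.triggered_rows) == 0
        assert res.total_triggered_length_um == 0.0

    def test_two_disjoint_stretches(self, params):
        fib = make_fiber((0, 0, 10), (1, 0, 0), 100, 1.0)   # 101 points
        f = np.zeros(len(fib))
        f[10:20] = 5.0    # 10 compartments -> 10 μm
        f[50:65] = 4.0    # 15 compartments -> 15 μm
        res = trigger_region(f, fib, params, True)
        assert res.total_triggered_length_um == pytest.approx(25.0)

    def test_hyperpolarizing_side_never_triggers(self, params):
        fib = make_fiber((0, 0, 10), (1, 0, 0), 100, 1.0)
        res = trigger_region(np.full(len(fib), -100.0), fib, params, True)
        assert res.total_triggered_length_um == 0.0

    def test_unmyelinated_threshold_is_20x(self, params):
        fib = make_fiber((0, 0, 10), (1, 0, 0), 100, 1.0)
        f = np.full(len(fib), 30.0)    # above 3, below 60
        assert trigger_region(f, fib, params, True
                              ).total_triggered_length_um > 0
        assert trigger_region(f, fib, params, False
                              ).total_triggered_length_um == 0

    def test_current_sign_flip_swaps_triggered_set(self, anodal_plate,
                                                   params,
                                                   horizontal_fiber):
        f_an = activating_function(horizontal_fiber, anodal_plate, params)
        f_ca = activating_function(horizontal_fiber,
                                   anodal_plate.with_current(-100.0), params)
        r_an = trigger_region(f_an, horizontal_fiber, params, True)
        r_ca = trigger_region(f_ca, horizontal_fiber, params, True)
        trig_an = set(r_an.triggered_rows.tolist())
        trig_ca = set(r_ca.triggered_rows.tolist())
        assert trig_an.isdisjoint(trig_ca)
        assert trig_ca == set(np.flatnonzero(-f_an >= params.threshold(True)))


class TestSpikeProbability:
    def test_zero_length(self, params):
        assert spike_probability(0.0, params, True) == 0.0
        assert spike_probability(0.0, params, False) == 0.0

    def test_closed_form_value(self, params):
        # L=100, D=100, k=1: p = 1 - 0.99^100
        assert spike_probability(100.0, params, True) \
            == pytest.approx(1.0 - 0.99 ** 100)

    def test_unmyelinated_binary(self, params):
        assert spike_probability(0.5, params, False) == 1.0

    def test_negative_length_rejected(self, params):
        with pytest.raises(ValueError):
            spike_probability(-1.0, params, True)

    @pytest.mark.parametrize("L", [1.0, 10.0, 50.0, 100.0, 300.0])
    def test_monte_carlo_oracle(self, params, L):
        """Bernoulli-segment simulation reproduces the closed form."""
        rng = np.random.default_rng(12345)
        n_draws = 100_000
        n_seg = int(round(L / params.node_length_k_um))
        p_node = params.node_length_k_um / params.internode_d_um
        any_node = (rng.random((n_draws, n_seg)) < p_node).any(axis=1)
        mc = any_node.mean()
        se = max(np.sqrt(mc * (1 - mc) / n_draws), 1e-6)
        assert abs(spike_probability(L, params, True) - mc) < 3 * se

    @given(st.floats(min_value=0.0, max_value=1e4),
           st.floats(min_value=0.0, max_value=1e4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, l1, l2):
        p = ActivationParams()
        lo, hi = sorted([l1, l2])
        p_lo = spike_probability(lo, p, True)
        p_hi = spike_probability(hi, p, True)
        assert 0.0 <= p_lo <= p_hi <= 1.0

    def test_limit_to_one(self, params):
        assert spike_probability(1e6, params, True) == pytest.approx(1.0)
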