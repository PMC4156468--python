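"""Ensemble construction, paracrine exchange and uncoupled-limit checks."""

import numpy as np
import pytest

from fofr import CellParameters, Protocol, simulate_cell
from fofr.model import initial_concentrations
from fofr.network import (D_TIME_UNIT, NetworkSpec, build_network,
                          sensed_vip, simulate_network)
from fofr.params import PIDX
from fofr.species import IDX, N_SPECIES


@pytest.fixture(scope="module")
def base():
    return CellParameters()


class TestBuildNetwork:
    def test_seeded_draws_are_reproducible(self, base):
        spec = NetworkSpec(n_cells=12, base_params=base, rate_jitter=0.2,
                           initial_jitter=0.2, seed=5)
        a, b = build_network(spec), build_network(spec)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.y0, b.y0)

    def test_different_seed_changes_draws(self, base):
        s1 = NetworkSpec(n_cells=5, base_params=base, rate_jitter=0.2,
                         seed=1)
        s2 = NetworkSpec(n_cells=5, base_params=base, rate_jitter=0.2,
                         seed=2)
        assert not np.allclose(build_network(s1).P, build_network(s2).P)

    def test_draws_within_stated_interval(self, base):
        w = 0.2
        spec = NetworkSpec(n_cells=200, base_params=base, rate_jitter=w,
                           initial_jitter=w, seed=3)
        net = build_network(spec)
        from fofr.params import PARAM_NAMES
        base_v = base.vector()
        keep = np.array([v != 0 and n not in ("atp_clamped",
                                              "per_independent_fraction")
                         for n, v in zip(PARAM_NAMES, base_v)])
        r = net.P[:, keep] / base_v[keep]
        assert r.min() >= 1 - w - 1e-12 and r.max() <= 1 + w + 1e-12

    def test_zero_width_gives_identical_cells(self, base):
        spec = NetworkSpec(n_cells=4, base_params=base, seed=0)
        net = build_network(spec)
        assert np.ptp(net.P, axis=0).max() == 0.0
        assert np.ptp(net.y0, axis=0).max() == 0.0

    def test_subgroup_override_yields_two_parameter_sets(self, base):
        spec = NetworkSpec(
            n_cells=20, base_params=base, seed=0,
            subgroups=((list(range(4, 20)),
                        {"g_CNG0": base.g_CNG0 / 2}),))
        net = build_network(spec)
        g = net.P[:, PIDX["g_CNG0"]]
        assert set(np.round(g, 12)) == {base.g_CNG0, base.g_CNG0 / 2}

    def test_invalid_override_names_parameter(self, base):
        with pytest.raises(ValueError, match="not_a_rate"):
            NetworkSpec(n_cells=2, base_params=base,
                        subgroups=(([0], {"not_a_rate": 1.0}),))

    def test_invalid_schedule_rejected(self, base):
        with pytest.raises(ValueError, match="increasing"):
            NetworkSpec(n_cells=2, base_params=base,
                        coupling_schedule=((10.0, 0.5), (0.0, 0.0)))


class TestSensedVip:
    def test_zero_coupling_is_inert(self):
        dL, dpool = sensed_vip(np.array([1.0, 2.0]), 5.0, 0.0)
        assert np.all(dL == 0.0) and dpool == 0.0

    def test_exchange_conserves_total_vip(self):
        """Volume-weighted VIP is conserved by the exchange fluxes alone."""
        rng = np.random.default_rng(0)
        for rho in (0.5, 1.0, 3.0):
            L = rng.uniform(0, 5, 20)
            pool = 1.3
            dL, dpool = sensed_vip(L, pool, 0.7, pool_volume_ratio=rho)
            n = L.size
            # unit cell volumes; pool volume rho * n
            assert dL.sum() + rho * n * dpool == pytest.approx(0.0, abs=1e-12)

    def test_strong_coupling_equalizes_sensed_vip(self, base):
        """With very large D all cells' local VIP converges to the pool."""
        spec = NetworkSpec(n_cells=3, base_params=base, seed=1,
                           initial_jitter=0.2,
                           coupling_schedule=((0.0, 500.0),))
        net = build_network(spec)
        tr = simulate_network(net, 1800.0, dt_out=30.0)
        L = tr.species("L")[-1]
        assert np.ptp(L) < 1e-3 * max(L.mean(), 1e-9)


def test_uncoupled_network_matches_independent_cells(base):
    """With D = 0 every cell evolves exactly like an isolated cell started
    from the same state (to solver tolerance)."""
    spec = NetworkSpec(n_cells=3, base_params=base, rate_jitter=0.1,
                       initial_jitter=0.1, seed=9)
    net = build_network(spec)
    T = 3 * 3600.0
    tr = simulate_network(net, T, dt_out=60.0, rtol=1e-8, atol=1e-11)
    for i in range(3):
        p_i = CellParameters.from_vector(net.P[i])
        solo = simulate_cell(p_i, Protocol.free_running(T),
                             init=net.y0[i, :N_SPECIES], dt_out=60.0,
                             rtol=1e-8, atol=1e-11)
        a = tr.Y[-1, i, :N_SPECIES]
        b = solo.y[-1]
        mask = np.abs(b) > 1e-3
        assert np.abs(a[mask] - b[mask]).max() / np.abs(b[mask]).max() < 5e-3


def test_cell_order_permutation_leaves_statistics_invariant(base):
    """Relabeling cells changes nothing about population statistics."""
    spec = NetworkSpec(n_cells=6, base_params=base, rate_jitter=0.15,
                       initial_jitter=0.15, seed=4,
                       coupling_schedule=((0.0, 0.5),))
    net = build_network(spec)
    perm = np.array([3, 1, 5, 0, 4, 2])
    net2 = build_network(spec)
    net2.P = net2.P[perm]
    net2.y0 = net2.y0[perm]
    t1 = simulate_network(net, 1800.0, dt_out=60.0)
    t2 = simulate_network(net2, 1800.0, dt_out=60.0)
    f1 = np.sort(t1.firing_rates[-1])
    f2 = np.sort(t2.firing_rates[-1])
    np.testing.assert_allclose(f1, f2, rtol=1e-4, atol=1e-6)
    np.testing.assert_allclose(t1.pool[-1], t2.pool[-1], rtol=1e-5,
                               atol=1e-8)
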