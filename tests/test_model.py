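"""Single-cell right-hand-side contracts: fixed point, conservation,
kernel equivalence, and the membrane transfer functions."""

import numpy as np
import pytest

from fofr import CellParameters, cng_conductance, firing_rate_from_current, \
    vip_release_rate
from fofr import _kernel  # noqa: F401  (import check)
from fofr.model import initial_concentrations, rhs
from fofr.species import (CONSERVED_MOIETIES, IDX, N_SPECIES,
                          conserved_totals)


def test_basal_state_is_fixed_point(params, basal):
    d = rhs(basal, params.vector(), vip_clamped=True, secretion_on=False)
    assert np.abs(d).max() < 1e-8


def test_zero_atp_cannot_synthesize_camp(params, basal):
    y = basal.copy()
    y[IDX["ATP"]] = 0.0
    y[IDX["GaACATP"]] = 0.0
    y[IDX["ACATP"]] = 0.0
    d = rhs(y, params.vector())
    assert d[IDX["cAMP"]] <= 0.0


def test_receptor_cycle_is_closed(params, basal):
    """Sum of receptor-species derivatives vanishes: recycling conserves
    total receptor rather than synthesising new ones."""
    rng = np.random.default_rng(7)
    w = CONSERVED_MOIETIES["receptor"]
    for _ in range(10):
        y = basal * rng.uniform(0.5, 2.0, N_SPECIES)
        d = rhs(y, params.vector())
        assert abs(d @ w) < 1e-10 * max(1.0, np.abs(d).max())


@pytest.mark.parametrize("moiety", sorted(CONSERVED_MOIETIES))
def test_mass_conservation_along_trajectory(free_run_8h, moiety):
    """Each closed reaction cycle conserves its weighted total to <= 1e-9
    relative over an 8-h free-running trajectory."""
    totals = free_run_8h.y @ CONSERVED_MOIETIES[moiety]
    rel = np.abs(totals - totals[0]) / max(abs(totals[0]), 1e-12)
    assert rel.max() < 1e-6  # solver-tolerance-limited; see rhs-level test


def test_rhs_conserves_every_moiety_exactly(params, basal):
    """At the RHS level conservation is exact to arithmetic precision."""
    rng = np.random.default_rng(3)
    P = params.vector()
    for _ in range(20):
        y = basal * rng.uniform(0.2, 5.0, N_SPECIES)
        d = rhs(y, P)
        for name, w in CONSERVED_MOIETIES.items():
            assert abs(d @ w) < 1e-9 * max(1.0, np.abs(d).max()), name


def test_compiled_kernel_matches_numpy_rhs(params, basal):
    """The numba fast path reproduces the reference RHS to machine
    precision on random states, in every clamp mode."""
    rng = np.random.default_rng(11)
    P = params.vector()
    for _ in range(30):
        y = basal * rng.uniform(0.1, 10.0, N_SPECIES)
        for clamped, secr in ((False, True), (True, False), (False, False)):
            a = rhs(y, P, vip_clamped=clamped, secretion_on=secr)
            b = _kernel.cell_rhs_single(y, P, clamped, secr, 0.0)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)


def test_invalid_state_rejected(params):
    from fofr.cell import _check_state
    y = initial_concentrations(params)
    y[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        _check_state(y)
    y = initial_concentrations(params)
    y[3] = -1.0
    with pytest.raises(ValueError, match="negative"):
        _check_state(y)


class TestCNGConductance:
    def test_fully_per_driven_channels_ignore_camp(self, params):
        P = params.replace(per_independent_fraction=1.0).vector()
        g = cng_conductance(np.array([0.0, 50.0, 5000.0]), 2.0, P)
        assert np.ptp(g) < 1e-12

    def test_zero_activators_give_zero_conductance(self, params):
        assert cng_conductance(0.0, 0.0, params.vector()) == 0.0

    def test_monotone_nondecreasing_in_camp(self, params):
        grid = np.linspace(0.0, 2000.0, 400)
        g = cng_conductance(grid, 0.0, params.vector())
        assert np.all(np.diff(g) >= -1e-15)
        assert g.max() <= params.g_CNG0 + 1e-12


class TestFiringTransfer:
    def test_subthreshold_is_silent(self, params):
        P = params.vector()
        assert firing_rate_from_current(params.I_threshold * 0.99, P) == 0.0

    def test_saturates(self, params):
        P = params.vector()
        f1 = firing_rate_from_current(params.I_sat * 2, P)
        f2 = firing_rate_from_current(params.I_sat * 4, P)
        assert f1 == f2 == params.F_max

    def test_monotone_and_bounded(self, params):
        P = params.vector()
        grid = np.linspace(0.0, 1.0, 200)
        f = firing_rate_from_current(grid, P)
        assert np.all(np.diff(f) >= 0.0)
        assert f.min() >= 0.0 and f.max() <= params.F_max


class TestSecretion:
    def test_flux_nondecreasing_in_rate(self, params):
        P = params.vector()
        r = vip_release_rate(np.linspace(0, 20, 50), P)
        assert np.all(np.diff(r) >= 0.0) and r[0] == 0.0

    def test_silent_cell_relaxes_to_vip0(self, params):
        """With zero firing, free VIP settles at VIP_0 (clearance balance)."""
        from fofr import Protocol, simulate_cell
        p = params.replace(g_CNG0=0.0)   # loop severed, firing always 0
        y0 = initial_concentrations(p)
        y0[IDX["L"]] = 5.0 * p.VIP_0
        traj = simulate_cell(p, Protocol.free_running(4 * 3600.0), init=y0,
                             dt_out=30.0)
        assert abs(traj.species("L")[-1] - p.VIP_0) < 1e-3
        assert traj.firing_rate.max() == 0.0
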