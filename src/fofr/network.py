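"""Heterogeneous multicellular ensemble with paracrine VIP exchange.

Each of the ``n_cells`` cells carries the full 47-species signalling state
(plus, optionally, a 16-variable circadian clock).  Cells communicate only
through VIP: each cell's perimembrane VIP pool exchanges first-order with a
single well-mixed extracellular pool at rate ``D / D_TIME_UNIT`` per
second.  D = 0 decouples the cells exactly; in the strong-coupling limit
every cell senses the common pool concentration.

Heterogeneity: every rate constant and every initial concentration is drawn
uniformly from [x0*(1-w), x0*(1+w)] per cell (seeded, reproducible), after
which explicit subgroup overrides are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from . import model
from .cell import SolverError
from .clock import (CLOCK_SPECIES, ClockParameters, clock_rhs,
                    creb_activity_from_pka)
from .model import rhs
from .params import PARAM_NAMES, PIDX, CellParameters
from .species import IDX, N_SPECIES, SURFACE_RECEPTOR, TOTAL_RECEPTOR

__all__ = ["NetworkSpec", "Network", "NetworkTrajectory", "build_network",
           "simulate_network", "sensed_vip", "D_TIME_UNIT"]

#: the paper's dimensionless D values are exchange rates per this many
#: seconds: D=0.5 -> 5e-3 s^-1, comparable to the VIP clearance rate, so the
#: published values 0.3 / 0.5 / 6 span weak -> strong coupling.
D_TIME_UNIT = 100.0

#: parameters never jittered: flags and structural fractions
_NO_JITTER = {"atp_clamped", "per_independent_fraction"}


@dataclass
class NetworkSpec:
    n_cells: int
    base_params: CellParameters = field(default_factory=CellParameters)
    rate_jitter: float = 0.0        # relative half-width on rate constants
    initial_jitter: float = 0.0     # relative half-width on initial concs
    seed: int = 0
    coupling_schedule: tuple = ((0.0, 0.0),)   # ((t_s, D), ...) increasing t
    subgroups: tuple = ()           # ((cell_indices, {param: value}), ...)
    totals: dict | None = None      # initial-pool overrides for all cells
    pool_volume_ratio: float = 1.0  # extracellular pool volume per cell vol
    with_clock: bool = False
    clock_params: ClockParameters = field(default_factory=ClockParameters)
    clock_jitter: float = 0.0       # relative half-width on clock parameters
    clock_phase_shifts_h: np.ndarray | None = None  # per-cell, hours

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for w in (self.rate_jitter, self.initial_jitter, self.clock_jitter):
            if not 0.0 <= w < 1.0:
                raise ValueError("jitter half-widths must lie in [0, 1)")
        ts = [t for t, _ in self.coupling_schedule]
        if sorted(ts) != ts:
            raise ValueError("coupling schedule times must be increasing")
        if any(d < 0 for _, d in self.coupling_schedule):
            raise ValueError("coupling strengths must be >= 0")
        for idx, ov in self.subgroups:
            for name in ov:
                if name not in PARAM_NAMES:
                    raise ValueError(
                        f"subgroup override targets unknown parameter "
                        f"{name!r}")


@dataclass
class Network:
    spec: NetworkSpec
    P: np.ndarray                  # (n_cells, n_params)
    y0: np.ndarray                 # (n_cells, n_comp) initial states
    CP: np.ndarray | None = None   # (n_cells, n_clock_params)
    pool0: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.spec.n_cells

    @property
    def n_comp(self) -> int:
        return self.y0.shape[1]


def _jitter(rng: np.random.Generator, x0: np.ndarray, w: float) -> np.ndarray:
    if w == 0.0:
        return x0.copy()
    return x0 * rng.uniform(1.0 - w, 1.0 + w, size=x0.shape)


def build_network(spec: NetworkSpec) -> Network:
    """Draw the heterogeneous ensemble (reproducible from ``spec.seed``).

    Per-cell parameter vectors are drawn uniformly within the relative
    half-widths, then subgroup overrides are applied, then each cell's
    initial state is its own jittered copy of the base resting state.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    base = spec.base_params.vector()
    P = np.tile(base, (n, 1))
    if spec.rate_jitter > 0:
        jmask = np.array([name not in _NO_JITTER for name in PARAM_NAMES])
        P[:, jmask] = _jitter(rng, P[:, jmask], spec.rate_jitter)
    for idx, overrides in spec.subgroups:
        for name, value in overrides.items():
            P[np.asarray(idx, int), PIDX[name]] = value

    y_base = model.initial_concentrations(spec.base_params, spec.totals)
    Y0 = np.tile(y_base, (n, 1))
    if spec.initial_jitter > 0:
        Y0 = _jitter(rng, Y0, spec.initial_jitter)

    CP = None
    if spec.with_clock:
        from .clock import limit_cycle_state
        cbase = spec.clock_params.vector()
        CP = np.tile(cbase, (n, 1))
        if spec.clock_jitter > 0:
            CP = _jitter(rng, CP, spec.clock_jitter)
        c0 = limit_cycle_state(spec.clock_params)
        C0 = np.tile(c0, (n, 1))
        shifts = spec.clock_phase_shifts_h
        if shifts is not None:
            C0 = _phase_shifted_states(spec.clock_params, np.asarray(shifts))
        Y0 = np.concatenate([Y0, C0], axis=1)
    return Network(spec, P, Y0, CP, pool0=float(spec.base_params.VIP_0))


def _phase_shifted_states(clock_params: ClockParameters,
                          shifts_h: np.ndarray) -> np.ndarray:
    """Clock states advanced by per-cell phase shifts along the limit cycle."""
    from .clock import limit_cycle_state
    from scipy.integrate import solve_ivp
    c0 = limit_cycle_state(clock_params)
    CPv = clock_params.vector()
    tmax = float(np.max(shifts_h)) if shifts_h.size else 0.0
    if tmax <= 0:
        return np.tile(c0, (shifts_h.size, 1))
    sol = solve_ivp(lambda t, c: clock_rhs(c, CPv), (0.0, tmax + 1e-3), c0,
                    method="LSODA", rtol=1e-9, atol=1e-11, dense_output=True)
    return np.stack([sol.sol(min(s, tmax)) for s in shifts_h])


def sensed_vip(local_vips: np.ndarray, pool_vip: float, D: float,
               pool_volume_ratio: float = 1.0):
    """Exchange fluxes between per-cell VIP pools and the common pool.

    Returns (dL_cells, dpool): each cell gains D*(pool - L_i) (s^-1 after
    unit conversion); the pool, scaled by its volume ratio, receives the
    opposite fluxes, so total volume-weighted VIP is conserved by the
    exchange terms alone.
    """
    L = np.asarray(local_vips, float)
    d = D / D_TIME_UNIT
    dL = d * (pool_vip - L)
    dpool = (d / pool_volume_ratio) * float(np.mean(L - pool_vip))
    return dL, dpool


@dataclass
class NetworkTrajectory:
    t: np.ndarray                  # shared grid (s)
    Y: np.ndarray                  # (nt, n_cells, n_comp)
    pool: np.ndarray               # (nt,)
    D: np.ndarray                  # (nt,)
    network: Network

    @property
    def n_cells(self) -> int:
        return self.Y.shape[1]

    def species(self, name: str) -> np.ndarray:
        """(nt, n_cells) series of one signalling or clock species."""
        if name in IDX:
            return self.Y[:, :, IDX[name]]
        return self.Y[:, :, N_SPECIES + CLOCK_SPECIES.index(name)]

    @property
    def firing_rates(self) -> np.ndarray:
        per = (self.Y[:, :, N_SPECIES + 0]
               if self.Y.shape[2] > N_SPECIES else 0.0)
        return np.stack([
            model.firing_rate(self.Y[k, :, :N_SPECIES], self.network.P,
                              per[k] if np.ndim(per) else 0.0)
            for k in range(self.t.size)])

    @property
    def surface_fractions(self) -> np.ndarray:
        ys = self.Y[:, :, :N_SPECIES]
        tot = ys @ TOTAL_RECEPTOR
        return (ys @ SURFACE_RECEPTOR) / np.where(tot > 0, tot, 1.0)

    def to_dataframe(self) -> pd.DataFrame:
        F = self.firing_rates
        frames = []
        for i in range(self.n_cells):
            frames.append(pd.DataFrame({
                "time_s": self.t, "cell": i,
                "firing_rate_hz": F[:, i],
                "vip_local": self.species("L")[:, i],
                "camp": self.species("cAMP")[:, i]}))
        return pd.concat(frames, ignore_index=True)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=self.t)
            f.create_dataset("pool_vip", data=self.pool)
            f.create_dataset("coupling", data=self.D)
            for i in range(self.n_cells):
                g = f.create_group(f"cell_{i:03d}")
                g.create_dataset("state", data=self.Y[:, i])
                g.attrs["params"] = self.network.P[i]


def _network_rhs(flat, net: Network, D: float):
    # finite-difference Jacobian probing can briefly pass extreme values;
    # the solver rejects such steps, so transient overflows are benign
    with np.errstate(over="ignore", invalid="ignore"):
        return _network_rhs_inner(flat, net, D)


def _network_rhs_inner(flat, net: Network, D: float):
    n, ncomp = net.n_cells, net.n_comp
    Y = flat[:-1].reshape(n, ncomp)
    pool = flat[-1]
    ys = Y[:, :N_SPECIES]
    out = np.empty_like(flat)
    dY = out[:-1].reshape(n, ncomp)
    if ncomp > N_SPECIES:
        C = Y[:, N_SPECIES:]
        per = C[:, 0]
        creb = creb_activity_from_pka(
            np.clip(ys[:, IDX["PKAn"]], 0.0, None),
            net.spec.clock_params.K_pkan)
        dY[:, N_SPECIES:] = clock_rhs(C, net.CP, creb) / 3600.0
    else:
        per = 0.0
    dL_x, dpool = sensed_vip(ys[:, IDX["L"]], pool, D,
                             net.spec.pool_volume_ratio)
    from . import _kernel
    if _kernel.HAVE_NUMBA:
        per_arr = (np.ascontiguousarray(per) if np.ndim(per)
                   else np.zeros(n))
        ex = dL_x if D > 0 else np.zeros(n)
        dY[:, :N_SPECIES] = _kernel.network_rhs_batch(
            np.ascontiguousarray(ys), net.P, per_arr,
            np.ascontiguousarray(ex))
    else:
        dY[:, :N_SPECIES] = rhs(ys, net.P, per_product=per,
                                extra_dL=dL_x if D > 0 else None)
    out[-1] = dpool if D > 0 else 0.0
    return out


def _sparsity(net: Network):
    n, ncomp = net.n_cells, net.n_comp
    N = n * ncomp + 1
    S = lil_matrix((N, N), dtype=np.int8)
    block = np.ones((ncomp, ncomp), dtype=np.int8)
    for i in range(n):
        S[i * ncomp:(i + 1) * ncomp, i * ncomp:(i + 1) * ncomp] = block
    iLs = [i * ncomp + IDX["L"] for i in range(n)]
    S[iLs, -1] = 1
    S[-1, iLs] = 1
    S[-1, -1] = 1
    return S.tocsc()


def simulate_network(net: Network, duration: float, *, rtol: float = 1e-6,
                     atol: float = 1e-9, dt_out: float = 30.0
                     ) -> NetworkTrajectory:
    """Integrate the coupled ensemble through its coupling schedule.

    One ODE system of n_cells * n_comp + 1 states (BDF with a block
    structured Jacobian sparsity); integration restarts at every D switch.
    """
    sched = list(net.spec.coupling_schedule)
    if not sched or sched[0][0] > 0:
        sched = [(0.0, 0.0)] + sched
    times = [t for t, _ in sched] + [duration]
    flat0 = np.concatenate([net.y0.ravel(), [net.pool0]])
    S = _sparsity(net)

    ts, Ys, Ds = [], [], []
    flat = flat0
    for k, (t0, D) in enumerate(sched):
        t1 = min(times[k + 1], duration)
        if t1 <= t0:
            continue
        t_eval = np.arange(t0, t1, dt_out)
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(lambda t, y: _network_rhs(y, net, D), (t0, t1), flat,
                        method="BDF", rtol=rtol, atol=atol,
                        t_eval=t_eval, jac_sparsity=S)
        if not sol.success:
            # cell-level diagnostics: largest-residual cell
            Ylast = sol.y[:-1, -1].reshape(net.n_cells, net.n_comp)
            resid = np.abs(_network_rhs(sol.y[:, -1], net, D))
            worst = int(resid[:-1].reshape(net.n_cells, -1)
                        .max(axis=1).argmax())
            raise SolverError(
                f"network integration failed (worst cell {worst})",
                sol.t[-1] if sol.t.size else t0)
        sl = slice(1, None) if ts else slice(None)
        ts.append(sol.t[sl])
        Ys.append(sol.y[:, sl].T)
        Ds.append(np.full(sol.t[sl].size, D))
        flat = sol.y[:, -1]
        if t1 >= duration:
            break
    t = np.concatenate(ts)
    flat_all = np.concatenate(Ys, axis=0)
    Y = flat_all[:, :-1].reshape(t.size, net.n_cells, net.n_comp)
    return NetworkTrajectory(t, np.clip(Y, 0.0, None),
                             np.clip(flat_all[:, -1], 0.0, None),
                             np.concatenate(Ds), net)
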