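"""Oscillation detection, phase/synchrony statistics and dynamical scans.

Conventions
-----------
* Oscillation criterion: cAMP (or any analyzed series) must keep cycling
  with peak-to-trough amplitude above ``rel_amplitude_threshold`` times its
  mean throughout the analysis window (15 h by default) after a transient
  trim (5 h by default).
* Period = mean inter-peak interval; amplitude = half the mean peak-to-
  trough excursion.
* Circadian phases are centers of mass of activity in successive 24-h
  windows; burst (FOFR) phases are burst-peak times folded on the
  population mean period and summarized with circular statistics.
* Equilibria returned by the nullcline and bifurcation scans are verified
  against the full right-hand side (residual below root tolerance);
  stability comes from the eigenvalues of a finite-difference Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.signal import find_peaks

from . import model
from .cell import Protocol, SolverError, basal_state, simulate_cell
from .model import rhs
from .params import ADDED_PARAMETERS, CellParameters
from .species import IDX, N_SPECIES, SPECIES_NAMES

__all__ = [
    "OscillationStats", "InsufficientDataError", "detect_oscillation",
    "estimate_period_amplitude", "compute_phases", "burst_phases",
    "sync_index", "phase_sd", "FastSubsystem", "vip_nullcline",
    "camp_vip_nullclines", "BifurcationScan", "scan_bifurcation",
    "sensitivity_scan",
]


class InsufficientDataError(ValueError):
    """Series too short (or too few cycles) for the requested statistic."""


@dataclass
class OscillationStats:
    oscillating: bool
    period_min: float = float("nan")
    amplitude: float = float("nan")
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))


def _peaks_troughs(t: np.ndarray, x: np.ndarray):
    span = float(x.max() - x.min())
    if span <= 0:
        return np.empty(0, int), np.empty(0, int)
    prom = 0.25 * span
    pk, _ = find_peaks(x, prominence=prom)
    tr, _ = find_peaks(-x, prominence=prom)
    return pk, tr


def detect_oscillation(t: np.ndarray, x: np.ndarray, *,
                       rel_amplitude_threshold: float = 0.1,
                       window: float = 15 * 3600.0,
                       transient: float = 5 * 3600.0) -> OscillationStats:
    """Decide whether ``x(t)`` keeps oscillating through the window.

    The first ``transient`` seconds are discarded; the remaining series
    must span at least ``window`` seconds (otherwise the call is undefined
    and raises :class:`InsufficientDataError`).  The flag is True iff the
    peak-to-trough excursion stays above ``rel_amplitude_threshold`` times
    the window mean in every third of the window and at least three peaks
    occur.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    sel = t >= transient
    t, x = t[sel], x[sel]
    if t.size < 8 or t[-1] - t[0] < window - 1e-6:
        raise InsufficientDataError(
            f"series spans {t[-1] - t[0] if t.size else 0:.0f} s "
            f"after transient; needs >= {window:.0f} s")
    # restrict to exactly one window
    sel = t <= t[0] + window
    t, x = t[sel], x[sel]
    mean = float(x.mean())
    if mean <= 0:
        return OscillationStats(False)
    thr = rel_amplitude_threshold * mean
    edges = np.linspace(t[0], t[-1], 4)
    for a, b in zip(edges[:-1], edges[1:]):
        seg = x[(t >= a) & (t <= b)]
        if seg.size == 0 or seg.max() - seg.min() < thr:
            return OscillationStats(False)
    pk, tr = _peaks_troughs(t, x)
    if pk.size < 3:
        return OscillationStats(False)
    period, amp = _period_amplitude(t, x, pk, tr)
    return OscillationStats(True, period, amp, t[pk])


def _period_amplitude(t, x, pk, tr):
    period = float(np.diff(t[pk]).mean()) / 60.0
    amp = 0.5 * float(x[pk].mean() - (x[tr].mean() if tr.size else x.min()))
    return period, amp


def estimate_period_amplitude(t: np.ndarray, x: np.ndarray, *,
                              transient: float = 0.0
                              ) -> tuple[float, float]:
    """(period [min], amplitude [series units, half peak-to-trough])."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    sel = t >= transient
    t, x = t[sel], x[sel]
    pk, tr = _peaks_troughs(t, x)
    if pk.size < 3:
        raise InsufficientDataError(f"need >= 3 peaks, found {pk.size}")
    return _period_amplitude(t, x, pk, tr)


def compute_phases(t: np.ndarray, activity: np.ndarray, *,
                   window: float = 24 * 3600.0,
                   subtract_baseline: bool = True) -> np.ndarray:
    """Center-of-mass phases of activity in successive windows.

    ``activity`` is (n_cells, n_times) and must be nonnegative.  Returns an
    (n_windows, n_cells) array of phases in seconds relative to each window
    start; windows with zero total activity give NaN.  With
    ``subtract_baseline`` each cell's within-window minimum is removed
    first, so a nonzero floor (e.g. an mRNA baseline) does not compress the
    center of mass toward the window midpoint; a constant series keeps its
    midpoint phase.
    """
    t = np.asarray(t, float)
    A = np.atleast_2d(np.asarray(activity, float))
    if np.any(A < -1e-12):
        raise ValueError("activity must be nonnegative")
    n_win = int((t[-1] - t[0]) // window)
    out = np.full((n_win, A.shape[0]), np.nan)
    for w in range(n_win):
        sel = (t >= t[0] + w * window) & (t < t[0] + (w + 1) * window)
        tw = t[sel] - (t[0] + w * window)
        Aw = A[:, sel]
        ok = Aw.sum(axis=1) > 0
        if subtract_baseline and Aw.size:
            base = Aw.min(axis=1, keepdims=True)
            Aw = np.where(Aw - base > 0, Aw - base, 0.0)
            flat = np.ptp(Aw, axis=1) <= 0
            Aw[flat] = 1.0  # constant activity: phase at window midpoint
        tot = Aw.sum(axis=1)
        ok &= tot > 0
        out[w, ok] = (Aw[ok] * tw).sum(axis=1) / tot[ok]
    return out


def burst_phases(t: np.ndarray, activity: np.ndarray, *,
                 t_start: float, t_stop: float
                 ) -> tuple[np.ndarray, float]:
    """Per-cell burst-peak phases folded on the population mean period.

    Finds each cell's burst peaks inside [t_start, t_stop], estimates the
    population mean burst period, and returns (phases_seconds, period_s)
    where phases are each cell's mean peak time modulo the period (circular
    mean).  Cells with no bursts give NaN.
    """
    t = np.asarray(t, float)
    A = np.atleast_2d(np.asarray(activity, float))
    sel = (t >= t_start) & (t <= t_stop)
    tw = t[sel]
    periods, peak_lists = [], []
    for x in A[:, sel]:
        pk, _ = _peaks_troughs(tw, x)
        peak_lists.append(tw[pk])
        if pk.size >= 2:
            periods.append(np.diff(tw[pk]).mean())
    if not periods:
        raise InsufficientDataError("no cell shows bursts in the window")
    T = float(np.mean(periods))
    phases = np.full(A.shape[0], np.nan)
    for i, pks in enumerate(peak_lists):
        if pks.size == 0:
            continue
        ang = 2 * np.pi * (pks % T) / T
        z = np.exp(1j * ang).mean()
        phases[i] = (np.angle(z) % (2 * np.pi)) * T / (2 * np.pi)
    return phases, T


def sync_index(phases: np.ndarray, cycle_length: float) -> float:
    """Order parameter SI in [0, 1]: |mean unit phase vector| on the cycle."""
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    if phases.size < 2:
        raise ValueError("need at least 2 phases")
    z = np.exp(2j * np.pi * phases / cycle_length)
    return float(np.abs(z.mean()))


def phase_sd(phases: np.ndarray, cycle_length: float) -> float:
    """Circular standard deviation of phases, in the phase units.

    Uses the circular SD sqrt(-2 ln R) mapped back to time units; for
    tightly clustered phases this coincides with the ordinary SD.
    """
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    if phases.size < 2:
        raise ValueError("need at least 2 phases")
    ang = 2 * np.pi * phases / cycle_length
    R = np.abs(np.exp(1j * ang).mean())
    R = min(R, 1.0)
    if R <= 0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(R)) * cycle_length / (2 * np.pi))


# ---------------------------------------------------------------------------
# fast-subsystem (clamped receptor) analysis
# ---------------------------------------------------------------------------

class FastSubsystem:
    """The signalling cascade with receptor trafficking frozen.

    The slow variables of the relaxation oscillator are the surface
    receptor pool (depleted by phosphorylation/internalization, restored by
    recycling).  Clamping them — receptor total fixed at a chosen surface
    availability, GRK pool emptied, no internalization or recycling —
    leaves the fast L/cAMP positive-feedback subsystem, whose equilibria
    and bistability underlie the N-shaped VIP nullcline.
    """

    def __init__(self, params: CellParameters, surface_receptor: float):
        self.params = params.replace(k_42=0.0, k_70=0.0, k_63=0.0,
                                     k_64=0.0, k_61=0.0)
        self.surface_receptor = float(surface_receptor)
        self.P = self.params.vector()
        self._warm: dict[float, np.ndarray] = {}

    def _initial(self) -> np.ndarray:
        y = basal_state(self.params)
        y = y.copy()
        # move all receptor mass to the unphosphorylated surface pool
        for s in ("R", "LR", "Rp", "LRp", "RGs", "LRGs", "LRpGs", "RpGs",
                  "Rint", "Rintp", "GRKpLR"):
            y[IDX[s]] = 0.0
        # GRK frozen in inactive form
        grk_tot = y[IDX["GRK"]] + y[IDX["GRKp"]] + y[IDX["PKACGRK"]]
        y[IDX["GRK"]] = grk_tot
        y[IDX["GRKp"]] = 0.0
        y[IDX["PKACGRK"]] = 0.0
        y[IDX["R"]] = self.surface_receptor
        return y

    def equilibrium(self, L: float, guess: np.ndarray | None = None
                    ) -> np.ndarray:
        """Steady state of the cascade with sensed VIP clamped to ``L``.

        The clamped cascade is relaxed by stiff integration (warm-started
        when a nearby solution is available) and polished by root-finding
        when the Jacobian permits; the integrated point is accepted as-is
        when its residual is already below tolerance.  The cascade given
        clamped VIP is attracting — the instability of the full cell lives
        in the VIP direction, which is scanned externally.
        """
        iL = IDX["L"]
        if guess is None:
            y = self._initial()
            horizon = 1.0e5
        else:
            y = guess.copy()
            horizon = 2.0e4
        y[iL] = L
        f = model.make_rhs(self.P, vip_clamped=True, secretion_on=False)
        for _ in range(3):
            sol = solve_ivp(f, (0.0, horizon), y, method="LSODA",
                            rtol=1e-9, atol=1e-11)
            y = np.clip(sol.y[:, -1], 0.0, None)
            y[iL] = L
            resid = np.abs(f(0.0, y)).max()
            if resid < 1e-8:
                break
            horizon *= 4
        mask = np.arange(N_SPECIES) != iL

        def res(z):
            yy = y.copy()
            yy[mask] = z
            return rhs(yy, self.P, vip_clamped=True,
                       secretion_on=False)[mask]

        sol2 = root(res, y[mask], method="hybr", tol=1e-13)
        if sol2.success and np.all(sol2.x > -1e-9):
            y[mask] = np.clip(sol2.x, 0.0, None)
        elif resid >= 1e-8:
            raise SolverError("fast-subsystem equilibrium did not converge",
                              0.0)
        return y

    def dL_dt(self, L: float, guess: np.ndarray | None = None) -> float:
        """Net free-VIP derivative with the cascade equilibrated at L."""
        if guess is None:
            guess = getattr(self, "_last", None)
        y = self.equilibrium(L, guess)
        self._last = y
        P = self.P
        F = model.firing_rate(y, P)
        return float(self.params.k_L * (self.params.VIP_0 - L)
                     + self.params.k_sec * F)

    def vip_equilibria(self, L_grid: np.ndarray) -> list[tuple[float, bool]]:
        """All roots of dL/dt (with fast cascade equilibrated) on the grid
        span.  Returns (L*, stable) pairs; stability is that of the scalar
        reduced dynamics (sign change of dL/dt)."""
        L_grid = np.asarray(L_grid, float)
        vals = []
        guess = None
        for L in L_grid:
            v = self.dL_dt(L, guess)
            guess = self._last
            vals.append(v)
        vals = np.asarray(vals)
        out = []
        for i in range(len(L_grid) - 1):
            a, b = vals[i], vals[i + 1]
            if a == 0.0:
                out.append((float(L_grid[i]), vals[min(i + 1, len(vals) - 1)] < 0))
            if a * b < 0:
                Ls = brentq(lambda LL: self.dL_dt(LL), L_grid[i],
                            L_grid[i + 1], xtol=1e-6)
                out.append((float(Ls), a > 0 > b))
        return out


def vip_nullcline(params: CellParameters, receptor_grid: np.ndarray, *,
                  L_grid: np.ndarray | None = None,
                  slow_recovery: bool = True) -> pd.DataFrame:
    """Equilibrium VIP vs clamped surface-receptor level (VIP nullcline).

    For each surface receptor amount, the fast subsystem is equilibrated
    and all VIP equilibria (up to three in the bistable range) are
    returned.  With ``slow_recovery`` the recycling rate is replaced by
    ``k_71`` (1e-8 s^-1 by default) before freezing, matching the
    slow-internalization limit in which the nullcline picture is exact.
    """
    if slow_recovery:
        params = params.replace(k_70=params.k_71)
    if L_grid is None:
        L_grid = np.geomspace(0.005, 50.0, 60)
    rows = []
    for rec in np.asarray(receptor_grid, float):
        fs = FastSubsystem(params, rec)
        try:
            eqs = fs.vip_equilibria(L_grid)
        except SolverError:
            rows.append((rec, np.nan, False, False))
            continue
        for L, stab in eqs:
            rows.append((rec, L, stab, True))
    return pd.DataFrame(rows, columns=["surface_receptor", "vip",
                                       "stable_fast", "converged"])


def camp_vip_nullclines(params: CellParameters, surface_receptor: float,
                        L_grid: np.ndarray) -> pd.DataFrame:
    """cAMP nullcline (cAMP equilibrated at clamped VIP) and VIP nullcline
    (VIP balancing secretion at given cAMP) in the VIP-cAMP plane, for a
    fixed surface receptor amount."""
    fs = FastSubsystem(params, surface_receptor)
    rows = []
    guess = None
    for L in np.asarray(L_grid, float):
        y = fs.equilibrium(L, guess)
        guess = y
        camp = y[IDX["cAMP"]]
        # VIP nullcline: L such that clearance balances secretion at this cAMP
        F = model.firing_rate(y, fs.P)
        L_null = params.VIP_0 + params.k_sec * F / params.k_L
        rows.append((L, camp, L_null))
    return pd.DataFrame(rows, columns=["vip", "camp_nullcline",
                                       "vip_nullcline"])


# ---------------------------------------------------------------------------
# bifurcation and sensitivity scans
# ---------------------------------------------------------------------------

#: scan targets resolved either to a rate parameter or to an initial total
_SCAN_TARGETS = {
    "VIP_0": ("param", "VIP_0"),
    "g_CNG0": ("param", "g_CNG0"),
    "I_threshold": ("param", "I_threshold"),
    "DE": ("param", "DE"),
    "k_61": ("param", "k_61"), "k_62": ("param", "k_62"),
    "k_63": ("param", "k_63"), "k_64": ("param", "k_64"),
    "k_42": ("param", "k_42"), "k_70": ("param", "k_70"),
    "tau_D": ("inverse_param", "k_70"),
    "AC_total": ("total", "AC"),
    "R_total": ("total", "R"),
    "GRK_total": ("total", "GRK"),
    "Gs_total": ("total", "Gs"),
    "PDE_total": ("total", "PDE"),
    "PKA_total": ("total", "R2C2"),
    "PKI_total": ("total", "PKI"),
    "ATP_total": ("total", "ATP"),
}


def _apply_target(params: CellParameters, name: str, value: float):
    """-> (params, totals overrides) realizing target ``name`` = value."""
    kind, key = _SCAN_TARGETS[name]
    if kind == "param":
        return params.replace(**{key: value}), None
    if kind == "inverse_param":
        return params.replace(**{key: 1.0 / value}), None
    return params, {key: value}


@dataclass
class BifurcationScan:
    parameter: str
    grid: np.ndarray
    table: pd.DataFrame  # value, eq_observable, stable, lc_min, lc_max, period_min


def _free_running_equilibrium(params: CellParameters,
                              totals: dict | None) -> tuple[np.ndarray, bool]:
    """Equilibrium of the full autocrine system and its linear stability."""
    P = params.vector()
    y0 = basal_state(params, totals)

    def f(y):
        return rhs(y, P, vip_clamped=False, secretion_on=True)

    sol = root(f, y0, method="hybr", tol=1e-12)
    y = sol.x if sol.success else y0
    # finite-difference Jacobian, relative step 1e-6
    n = y.size
    J = np.empty((n, n))
    f0 = f(y)
    for j in range(n):
        h = 1e-6 * max(abs(y[j]), 1e-3)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (f(yp) - f0) / h
    lam = np.linalg.eigvals(J)
    return y, bool(np.max(lam.real) < 1e-9)


def _oscillates(params: CellParameters, totals: dict | None, *,
                sim_hours: float = 20.0, transient: float = 5 * 3600.0,
                rtol: float = 1e-6) -> OscillationStats:
    try:
        init = model.initial_concentrations(params, totals)
        traj = simulate_cell(params, Protocol.free_running(sim_hours * 3600),
                             init=init, dt_out=20.0, rtol=rtol)
    except SolverError:
        return OscillationStats(False)
    return detect_oscillation(traj.t, traj.species("cAMP"),
                              transient=transient)


def scan_bifurcation(params: CellParameters, parameter: str,
                     grid: np.ndarray, *, observable: str = "cAMP",
                     sim_hours: float = 15.0) -> BifurcationScan:
    """Equilibrium branch + limit-cycle extrema along a parameter grid.

    Per grid point: the full-system equilibrium is located by root-finding
    (flagged stable/unstable via Jacobian eigenvalues) and the limit cycle
    is characterized by direct simulation after a transient.  Points where
    the root search fails are flagged (NaN) and the scan continues.
    """
    if parameter not in _SCAN_TARGETS:
        raise ValueError(f"unknown scan parameter {parameter!r}; "
                         f"choose from {sorted(_SCAN_TARGETS)}")
    rows = []
    for v in np.asarray(grid, float):
        p2, totals = _apply_target(params, parameter, v)
        try:
            yeq, stable = _free_running_equilibrium(p2, totals)
            eq_obs = float(yeq[IDX[observable]])
        except Exception:
            yeq, stable, eq_obs = None, False, float("nan")
        lc_min = lc_max = period = float("nan")
        try:
            traj = simulate_cell(p2, Protocol.free_running(sim_hours * 3600),
                                 init=basal_state(p2, totals), dt_out=20.0)
            x = traj.species(observable)
            sel = traj.t >= 5 * 3600.0
            xs = x[sel]
            try:
                per, _amp = estimate_period_amplitude(traj.t[sel], xs)
                # only a genuine cycle counts; near-equilibrium ripples do not
                if xs.max() - xs.min() > 0.02 * max(xs.mean(), 1e-12):
                    lc_min, lc_max, period = float(xs.min()), float(xs.max()), per
            except InsufficientDataError:
                pass
        except SolverError:
            pass
        rows.append((v, eq_obs, stable, lc_min, lc_max, period))
    table = pd.DataFrame(rows, columns=["value", "equilibrium", "stable",
                                        "lc_min", "lc_max", "period_min"])
    return BifurcationScan(parameter, np.asarray(grid, float), table)


def sensitivity_scan(params: CellParameters, *, factor: float = 50.0,
                     species: list[str] | None = None,
                     parameters: list[str] | None = None,
                     sim_hours: float = 20.0, rtol: float = 1e-6,
                     log_resolution: float = 0.02,
                     refine_ratios: bool = True) -> pd.DataFrame:
    """Oscillatory range of every initial concentration and added parameter.

    Each quantity x is varied in [x0/factor, x0*factor] (x0 = default).  A
    quantity is *critical* when oscillations (10% relative cAMP amplitude
    sustained 15 h after a 5-h transient) are lost somewhere inside that
    range; the surviving sub-range containing x0 is then bracketed by
    bisection in log space to ``log_resolution`` and reported as lo/hi with
    the boundary ratio hi/lo.  Non-critical quantities keep the full range
    (ratio = factor^2).
    """
    if not _oscillates(params, None, sim_hours=sim_hours,
                       rtol=rtol).oscillating:
        raise RuntimeError("base parameter set does not oscillate; "
                           "sensitivity scan aborted")

    y0 = model.initial_concentrations(params)

    def ok(kind, key, scale) -> bool:
        if kind == "species":
            return _oscillates_scaled_species(params, key, scale, y0,
                                              sim_hours, rtol)
        try:
            p2 = params.replace(**{key: getattr(params, key) * scale})
        except ValueError:
            # physically infeasible combination (e.g. threshold above
            # saturation): firing is impossible, so no oscillation
            return False
        return _oscillates(p2, None, sim_hours=sim_hours,
                           rtol=rtol).oscillating

    rows = []
    spc = species if species is not None else SPECIES_NAMES
    prm = parameters if parameters is not None else ADDED_PARAMETERS
    jobs = [("species", s) for s in spc] + [("parameter", k) for k in prm]
    for kind, key in jobs:
        k = "species" if kind == "species" else "param"
        lo_ok = ok(k, key, 1.0 / factor)
        hi_ok = ok(k, key, factor)
        critical = not (lo_ok and hi_ok)
        lo_scale, hi_scale = 1.0 / factor, factor
        if critical and refine_ratios:
            if not lo_ok:
                lo_scale = _bisect_boundary(ok, k, key, 1.0, 1.0 / factor,
                                            log_resolution)
            if not hi_ok:
                hi_scale = _bisect_boundary(ok, k, key, 1.0, factor,
                                            log_resolution)
        x0 = (float(y0[IDX[key]]) if kind == "species"
              else float(getattr(params, key)))
        rows.append((kind, key, x0, critical, x0 * lo_scale, x0 * hi_scale,
                     hi_scale / lo_scale if lo_scale > 0 else np.inf))
    return pd.DataFrame(rows, columns=["kind", "name", "default", "critical",
                                       "lo", "hi", "ratio"])


def _oscillates_scaled_species(params, key, scale, y0, sim_hours, rtol):
    init = y0.copy()
    init[IDX[key]] = init[IDX[key]] * scale
    try:
        traj = simulate_cell(params, Protocol.free_running(sim_hours * 3600),
                             init=init, dt_out=20.0, rtol=rtol)
    except SolverError:
        return False
    try:
        return detect_oscillation(traj.t, traj.species("cAMP")).oscillating
    except InsufficientDataError:
        return False


def _bisect_boundary(ok, kind, key, good_scale, bad_scale,
                     log_resolution) -> float:
    """Log-space bisection between an oscillating and a dead scale."""
    lg, lb = np.log(good_scale), np.log(bad_scale)
    while abs(lb - lg) > log_resolution:
        mid = 0.5 * (lg + lb)
        if ok(kind, key, float(np.exp(mid))):
            lg = mid
        else:
            lb = mid
    return float(np.exp(lg))
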