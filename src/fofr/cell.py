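"""Single-cell simulation: protocols, trajectories and step-response metrics.

Time is seconds everywhere internally; minutes appear only in reported
metrics (half-times, periods).  Integration uses a stiff variable-order
implicit solver (LSODA) and is restarted at every protocol discontinuity, so
clamp events are honored exactly.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import model
from .model import rhs
from .params import CellParameters
from .species import (IDX, N_SPECIES, SPECIES_NAMES, SURFACE_RECEPTOR,
                      TOTAL_RECEPTOR)

__all__ = [
    "ProtocolSegment", "Protocol", "CellTrajectory", "SolverError",
    "basal_state", "simulate_cell", "run_vip_step", "internalization_metrics",
    "ac_dose_response", "InternalizationStats",
]


class SolverError(RuntimeError):
    """Stiff integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:.1f} s)")
        self.last_time = last_time


@dataclass(frozen=True)
class ProtocolSegment:
    """One homogeneous stretch of a protocol.

    ``vip_clamp`` is a bath VIP concentration (nM) imposed on the sensed VIP
    during the segment, or None for free (autocrine) VIP.  Autocrine
    secretion is disabled whenever VIP is clamped, matching a
    bath-application experiment.
    """
    duration: float
    vip_clamp: float | None = None
    secretion_on: bool = True

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.vip_clamp is not None and self.vip_clamp < 0:
            raise ValueError("vip_clamp must be >= 0")


@dataclass(frozen=True)
class Protocol:
    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("protocol needs at least one segment")

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def free_running(cls, duration: float) -> "Protocol":
        return cls((ProtocolSegment(duration),))

    @classmethod
    def vip_step(cls, vip: float, on: float, washout: float) -> "Protocol":
        return cls((ProtocolSegment(on, vip_clamp=vip, secretion_on=False),
                    ProtocolSegment(washout, vip_clamp=0.0,
                                    secretion_on=False)))


@dataclass
class CellTrajectory:
    """Time grid (s), species matrix (nM) and derived series of one cell."""
    t: np.ndarray
    y: np.ndarray
    params: CellParameters
    per_product: np.ndarray | float = 0.0

    def species(self, name: str) -> np.ndarray:
        return self.y[:, IDX[name]]

    @property
    def cng_current(self) -> np.ndarray:
        return model.cng_current(self.y, self.params.vector(),
                                 self.per_product)

    @property
    def firing_rate(self) -> np.ndarray:
        return model.firing_rate(self.y, self.params.vector(),
                                 self.per_product)

    @property
    def surface_fraction(self) -> np.ndarray:
        tot = self.y @ TOTAL_RECEPTOR
        return (self.y @ SURFACE_RECEPTOR) / np.where(tot > 0, tot, 1.0)

    @property
    def ac_activity(self) -> np.ndarray:
        """Concentration of Galpha_s-AC complexes (nM, ATP-bound included)."""
        return self.y[:, IDX["GaAC"]] + self.y[:, IDX["GaACATP"]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=SPECIES_NAMES)
        df.insert(0, "time_s", self.t)
        df["firing_rate_hz"] = self.firing_rate
        df["surface_fraction"] = self.surface_fraction
        return df


def _check_state(y: np.ndarray) -> None:
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != N_SPECIES:
        raise ValueError(f"state must have {N_SPECIES} entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite concentrations")
    if np.any(y < -1e-9):
        raise ValueError("state contains negative concentrations")


@functools.lru_cache(maxsize=32)
def _basal_state_cached(pbytes: bytes, totals_items: tuple) -> np.ndarray:
    P = np.frombuffer(pbytes, dtype=float).copy()
    totals = dict(totals_items)
    y0 = model.assemble_resting_state(P, totals or None)
    vip0 = P[_pidx("VIP_0")]

    f = model.make_rhs(P, vip_clamped=True, secretion_on=False)
    sol = solve_ivp(f, (0.0, 2.0e5), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise SolverError("basal pre-equilibration failed", sol.t[-1])
    y = sol.y[:, -1]

    # refine to machine precision with the VIP clamp folded in
    iL = IDX["L"]

    def res(z):
        yy = y.copy()
        yy[np.arange(N_SPECIES) != iL] = z
        yy[iL] = vip0
        return np.delete(rhs(yy, P, vip_clamped=True, secretion_on=False), iL)

    sol2 = root(res, np.delete(y, iL), method="hybr", tol=1e-12)
    if sol2.success:
        y[np.arange(N_SPECIES) != iL] = sol2.x
    y[iL] = vip0
    y = np.clip(y, 0.0, None)
    y.setflags(write=False)
    return y


def _pidx(name: str) -> int:
    from .params import PIDX
    return PIDX[name]


def basal_state(params: CellParameters | None = None,
                totals: dict[str, float] | None = None) -> np.ndarray:
    """Silent resting state: equilibrium with VIP clamped at VIP_0.

    This is the model's default initial-concentration vector.  It is found
    by long pre-integration followed by multidimensional root refinement, so
    the returned state is a fixed point of the clamped right-hand side to
    root tolerance.
    """
    params = params or CellParameters()
    key = tuple(sorted((totals or {}).items()))
    return _basal_state_cached(params.vector().tobytes(), key).copy()


def simulate_cell(params: CellParameters, protocol: Protocol,
                  init: np.ndarray | None = None, *, rtol: float = 1e-6,
                  atol: float = 1e-9, dt_out: float = 5.0,
                  per_product: float = 0.0) -> CellTrajectory:
    """Integrate one cell through a protocol.

    Returns the trajectory on a uniform output grid (spacing ``dt_out`` s).
    Raises :class:`SolverError` with the last valid time if the stiff solver
    fails to converge.
    """
    params.validate()
    P = params.vector()
    y = basal_state(params) if init is None else np.array(init, dtype=float)
    _check_state(y)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    t0 = 0.0
    for k, seg in enumerate(protocol.segments):
        clamped = seg.vip_clamp is not None
        if clamped:
            y = y.copy()
            y[IDX["L"]] = seg.vip_clamp

        f = model.make_rhs(P, vip_clamped=clamped,
                           secretion_on=seg.secretion_on,
                           per_product=per_product)
        t1 = t0 + seg.duration
        t_eval = np.arange(t0, t1, dt_out)
        if t_eval.size == 0 or t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(f, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise SolverError(f"integration failed in segment {k}",
                              sol.t[-1] if sol.t.size else t0)
        # drop duplicated boundary sample of the previous segment
        sl = slice(1, None) if ts else slice(None)
        ts.append(sol.t[sl])
        ys.append(sol.y[:, sl].T)
        y = sol.y[:, -1]
        t0 = t1

    traj = CellTrajectory(np.concatenate(ts), np.clip(
        np.concatenate(ys, axis=0), 0.0, None), params)
    return traj


def run_vip_step(params: CellParameters, vip_conc: float, on_duration: float,
                 washout_duration: float, **kw) -> CellTrajectory:
    """Bath VIP step: sensed VIP clamped to ``vip_conc`` then to 0 (washout).

    Autocrine release is disabled for the whole protocol, as in a bath
    application experiment.
    """
    if vip_conc < 0:
        raise ValueError("vip_conc must be >= 0")
    proto = Protocol.vip_step(vip_conc, on_duration, washout_duration)
    return simulate_cell(params, proto, **kw)


@dataclass
class InternalizationStats:
    """Receptor-trafficking metrics of a VIP-step trajectory.

    ``defined`` is False when the step produced < 1% internalization, in
    which case every other field is NaN rather than zero.
    """
    defined: bool
    half_time_min: float = float("nan")
    max_internalization_pct: float = float("nan")
    recovery_half_time_min: float = float("nan")
    recovered_pct_at_1h: float = float("nan")


def _cross_time(t: np.ndarray, x: np.ndarray, level: float,
                rising: bool) -> float:
    """First time x crosses `level` (linear interpolation), NaN if never."""
    if rising:
        idx = np.nonzero(x >= level)[0]
    else:
        idx = np.nonzero(x <= level)[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    if i == 0:
        return float(t[0])
    f = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def internalization_metrics(traj: CellTrajectory,
                            step_window: tuple[float, float]
                            ) -> InternalizationStats:
    """Internalization/recovery metrics from a VIP-step trajectory.

    ``step_window`` is the (t_on, t_off) of the VIP application in seconds.
    Half-times are interpolated between samples; maximal internalization is
    100*(1 - min surface fraction / pre-step surface fraction).
    """
    t_on, t_off = step_window
    t = traj.t
    s = traj.surface_fraction
    i_on = int(np.searchsorted(t, t_on))
    i_off = int(np.searchsorted(t, t_off))
    s0 = s[i_on]
    if s0 <= 0:
        return InternalizationStats(defined=False)
    m = s / s0  # membrane fraction normalized to its pre-step value

    m_min = float(m[i_on:i_off + 1].min())
    max_int = 100.0 * (1.0 - m_min)
    if max_int < 1.0:
        return InternalizationStats(defined=False)

    t_half = _cross_time(t[i_on:i_off + 1], m[i_on:i_off + 1],
                         (1.0 + m_min) / 2.0, rising=False)
    half_time_min = (t_half - t_on) / 60.0

    stats = InternalizationStats(
        defined=True, half_time_min=half_time_min,
        max_internalization_pct=max_int)

    if i_off < t.size - 1:
        m_off = float(m[i_off])
        target = m_off + (1.0 - m_off) / 2.0
        t_rec = _cross_time(t[i_off:], m[i_off:], target, rising=True)
        stats.recovery_half_time_min = (t_rec - t_off) / 60.0
        i_1h = int(np.searchsorted(t, t_off + 3600.0))
        if i_1h < t.size:
            stats.recovered_pct_at_1h = 100.0 * float(m[i_1h])
    return stats


def ac_dose_response(params: CellParameters, test_concs,
                     desensitize_first: bool = False, *,
                     read_time: float = 120.0, rtol: float = 1e-6,
                     atol: float = 1e-9) -> np.ndarray:
    """AC activity (% of total AC engaged in Galpha_s-AC complexes) vs VIP.

    Each test concentration is applied as a clamp for ``read_time`` seconds
    (2 min by default) and activity is read at the end.  With
    ``desensitize_first`` the cell is first driven through 30 min of 1 uM
    VIP and a 5-min washout, as in the receptor-desensitization assay.
    """
    test_concs = np.asarray(test_concs, dtype=float)
    P = params.vector()
    y0 = basal_state(params)
    if desensitize_first:
        pre = simulate_cell(
            params, Protocol.vip_step(1000.0, 1800.0, 300.0), init=y0,
            rtol=rtol, atol=atol)
        y0 = pre.y[-1]

    ac_total = float(y0[IDX["AC"]] + y0[IDX["GaAC"]]
                     + y0[IDX["GaACATP"]] + y0[IDX["ACATP"]])
    out = np.empty(test_concs.size)
    for i, c in enumerate(test_concs):
        y = y0.copy()
        y[IDX["L"]] = c
        f = model.make_rhs(P, vip_clamped=True, secretion_on=False)
        sol = solve_ivp(f, (0.0, read_time), y, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError("dose-response integration failed", sol.t[-1])
        yf = sol.y[:, -1]
        out[i] = 100.0 * (yf[IDX["GaAC"]] + yf[IDX["GaACATP"]]) / ac_total
    return out
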