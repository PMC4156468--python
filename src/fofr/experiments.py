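"""Config-driven computational experiments.

Each experiment mirrors one of the published figures:

* ``fig2_step``     – bath VIP steps; cAMP time course and receptor
  internalization/recovery metrics.
* ``fig2_dose``     – AC activity vs VIP before/after desensitization.
* ``fig3_nullclines`` – VIP/VPAC2 phase-plane: N-shaped VIP nullcline in
  the slow-recovery limit and clamped-receptor fixed points.
* ``fig4_bifurcation`` – equilibrium/limit-cycle branches along key
  parameters.
* ``fig4_sensitivity`` – oscillatory ranges of initial concentrations and
  added parameters.
* ``fig5_sync50``   – 50-cell +/-20% heterogeneous ensemble; coupling
  switched on after free-running epoch.
* ``fig6_induction`` – 20 cells, 4 default + 16 at half CNG conductance;
  induction of network oscillations, coupling-strength series.
* ``fig7_circadian`` – 10-cell circadian networks in three
  regulation variants; series 1 (uniform phase spread, coupling on) and
  series 2 (3.5% clock jitter, coupling on then off).

Every result bundle records the seed, the configuration and the metrics
the corresponding figure reports.  Durations and ensemble sizes are
configurable; defaults follow the published protocols.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .analysis import (burst_phases, estimate_period_amplitude,
                       InsufficientDataError, phase_sd, sensitivity_scan,
                       scan_bifurcation, sync_index, vip_nullcline)
from .cell import ac_dose_response, internalization_metrics, run_vip_step
from .clock import configure_variant
from .network import NetworkSpec, NetworkTrajectory, build_network, \
    simulate_network
from .params import CellParameters

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "EXPERIMENTS", "default_parameters"]


def default_parameters() -> CellParameters:
    """The calibrated default cell."""
    return CellParameters()


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    def get(self, key, default):
        return self.overrides.get(key, default)


@dataclass
class ExperimentResult:
    experiment: str
    seed: int
    config: dict
    metrics: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    trajectory: object | None = None
    wall_time_s: float = 0.0

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w") as f:
            json.dump({"experiment": self.experiment, "seed": self.seed,
                       "config": self.config, "metrics": self.metrics,
                       "wall_time_s": self.wall_time_s},
                      f, indent=1, default=float)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        if isinstance(self.trajectory, NetworkTrajectory):
            self.trajectory.to_hdf5(out / "trajectories.h5")


# ---------------------------------------------------------------------------

def _fig2_step(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    concs = cfg.get("vip_steps_nM", [0.1, 1.0, 10.0, 100.0, 1000.0])
    on = cfg.get("on_s", 1800.0)
    wash = cfg.get("washout_s", 3600.0)
    rows, tables = [], {}
    for c in concs:
        traj = run_vip_step(p, c, on, wash, dt_out=5.0)
        st = internalization_metrics(traj, (0.0, on))
        camp = traj.species("cAMP")
        i_on = np.searchsorted(traj.t, on)
        ipk = int(np.argmax(camp[:i_on]))
        rows.append(dict(
            vip_nM=c, defined=st.defined,
            half_time_min=st.half_time_min,
            max_internalization_pct=st.max_internalization_pct,
            recovery_half_time_min=st.recovery_half_time_min,
            recovered_pct_at_1h=st.recovered_pct_at_1h,
            camp_peak_nM=float(camp[:i_on].max()),
            camp_peak_time_min=traj.t[ipk] / 60.0,
            camp_plateau_nM=float(camp[i_on - 1]),
        ))
        tables[f"trajectory_{c:g}nM"] = pd.DataFrame(
            {"time_s": traj.t, "camp_nM": camp,
             "surface_fraction": traj.surface_fraction})
    table = pd.DataFrame(rows)
    m1000 = table[table.vip_nM == 1000.0]
    metrics = ({} if m1000.empty else
               m1000.iloc[0].drop("vip_nM").to_dict())
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides,
                            metrics, {"step_metrics": table, **tables})


def _fig2_dose(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    concs = np.asarray(cfg.get(
        "test_concs_nM", np.geomspace(0.01, 3000.0, 13)))
    naive = ac_dose_response(p, concs, desensitize_first=False)
    desens = ac_dose_response(p, concs, desensitize_first=True)
    table = pd.DataFrame({"vip_nM": concs, "ac_naive_pct": naive,
                          "ac_desensitized_pct": desens})
    fold = float(naive.max() / desens.max())

    def ec50(c, a):
        half = a.max() / 2.0
        i = int(np.argmax(a >= half))
        if i == 0:
            return float(c[0])
        f = (half - a[i - 1]) / (a[i] - a[i - 1])
        return float(np.exp(np.log(c[i - 1])
                            + f * (np.log(c[i]) - np.log(c[i - 1]))))

    metrics = dict(max_fold_reduction=fold,
                   ec50_naive_nM=ec50(concs, naive),
                   ec50_desensitized_nM=ec50(concs, desens))
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides,
                            metrics, {"dose_response": table})


def _fig3_nullclines(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    rec_grid = np.asarray(cfg.get(
        "receptor_grid", np.linspace(20.0, 300.0, 15)))
    nc = vip_nullcline(p, rec_grid, slow_recovery=True)
    # clamped-receptor fixed-point structure at an intermediate level
    rec_mid = float(cfg.get("receptor_mid", 0.45 * rec_grid.max()))
    fs = analysis.FastSubsystem(
        p.replace(k_70=p.k_71), rec_mid)
    eqs = fs.vip_equilibria(np.geomspace(0.01, 30.0, 40))
    counts = nc.groupby("surface_receptor")["vip"].count()
    metrics = dict(
        max_equilibria=int(counts.max()),
        bistable_receptor_levels=int((counts >= 3).sum()),
        mid_level_fixed_points=len(eqs),
        mid_level_stable=int(sum(s for _, s in eqs)))
    table2 = pd.DataFrame(eqs, columns=["vip", "stable"])
    table2.insert(0, "surface_receptor", rec_mid)
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides, metrics,
                            {"vip_nullcline": nc,
                             "mid_level_fixed_points": table2})


def _fig4_bifurcation(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    scans = cfg.get("scans", {
        "VIP_0": np.geomspace(0.2, 5.0, 7) * p.VIP_0,
        "g_CNG0": np.geomspace(0.3, 3.0, 7) * p.g_CNG0,
        "tau_D": np.geomspace(0.3, 3.0, 7) / p.k_70,
    })
    tables, metrics = {}, {}
    for name, grid in scans.items():
        scan = scan_bifurcation(p, name, grid,
                                sim_hours=cfg.get("sim_hours", 12.0))
        tables[f"bifurcation_{name}"] = scan.table
        osc = scan.table.dropna(subset=["period_min"])
        if len(osc) >= 2:
            metrics[f"{name}_period_span_min"] = [
                float(osc.period_min.min()), float(osc.period_min.max())]
            if name == "tau_D":
                r = np.corrcoef(osc.value, osc.period_min)[0, 1]
                metrics["period_tauD_correlation"] = float(r)
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides,
                            metrics, tables)


def _fig4_sensitivity(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    table = sensitivity_scan(
        p, factor=cfg.get("factor", 50.0),
        species=cfg.get("species", None),
        parameters=cfg.get("parameters", None),
        sim_hours=cfg.get("sim_hours", 20.0),
        rtol=cfg.get("rtol", 1e-6),
        refine_ratios=cfg.get("refine_ratios", True))
    crit = table[table.critical].sort_values("ratio")
    metrics = dict(
        n_quantities=len(table),
        n_critical_species=int((table.critical
                                & (table.kind == "species")).sum()),
        most_sensitive=crit.name.head(4).tolist(),
        most_sensitive_ratios=[float(x) for x in crit.ratio.head(4)],
        min_noncritical_ratio=float(
            table[~table.critical].ratio.min()) if (~table.critical).any()
        else float("nan"))
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides,
                            metrics, {"sensitivity": table})


def _ensemble_stats(tr: NetworkTrajectory, t0: float, t1: float,
                    min_amp_hz: float = 0.05):
    """Per-cell oscillation stats of firing rate in [t0, t1]."""
    F = tr.firing_rates
    sel = (tr.t >= t0) & (tr.t <= t1)
    rows = []
    for i in range(tr.n_cells):
        try:
            per, amp = estimate_period_amplitude(tr.t[sel], F[sel, i])
            osc = amp >= min_amp_hz
        except InsufficientDataError:
            per, amp, osc = np.nan, 0.0, False
        rows.append(dict(cell=i, oscillating=bool(osc), period_min=per,
                         amplitude_hz=amp))
    return pd.DataFrame(rows)


def _fig5_sync50(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    n = cfg.get("n_cells", 50)
    jit = cfg.get("jitter", 0.2)
    t_on = cfg.get("coupling_on_s", 20 * 3600.0)
    post = cfg.get("post_s", 10 * 3600.0)
    D = cfg.get("D", 0.5)
    spec = NetworkSpec(n_cells=n, base_params=p, rate_jitter=jit,
                       initial_jitter=jit, seed=cfg.seed,
                       coupling_schedule=((0.0, 0.0), (t_on, D)))
    net = build_network(spec)
    tr = simulate_network(net, t_on + post,
                          dt_out=cfg.get("dt_out", 30.0),
                          rtol=cfg.get("rtol", 1e-6))
    pre = _ensemble_stats(tr, cfg.get("pre_window_s", 5 * 3600.0), t_on)
    post_tbl = _ensemble_stats(tr, t_on + 0.3 * post, t_on + post)
    F = tr.firing_rates
    try:
        ph, T = burst_phases(tr.t, F.T, t_start=t_on + 0.5 * post,
                             t_stop=t_on + post)
        sd_s = phase_sd(ph, T)
        si = sync_index(ph, T)
    except (InsufficientDataError, ValueError):
        ph, T, sd_s, si = None, np.nan, np.nan, np.nan
    osc_pre = pre[pre.oscillating]
    osc_post = post_tbl[post_tbl.oscillating]
    metrics = dict(
        n_cells=n,
        frac_oscillating_pre=float(pre.oscillating.mean()),
        period_pre_mean_min=float(osc_pre.period_min.mean()),
        period_pre_sd_min=float(osc_pre.period_min.std()),
        amplitude_pre_mean_hz=float(osc_pre.amplitude_hz.mean()),
        amplitude_pre_sd_hz=float(osc_pre.amplitude_hz.std()),
        frac_oscillating_post=float(post_tbl.oscillating.mean()),
        period_post_mean_min=float(osc_post.period_min.mean()),
        period_post_sd_min=float(osc_post.period_min.std()),
        amplitude_post_mean_hz=float(osc_post.amplitude_hz.mean()),
        amplitude_post_sd_hz=float(osc_post.amplitude_hz.std()),
        phase_sd_post_s=float(sd_s),
        sync_index_post=float(si),
        mean_burst_period_post_min=float(T / 60.0) if np.isfinite(T)
        else float("nan"))
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides, metrics,
                            {"pre_coupling": pre, "post_coupling": post_tbl},
                            trajectory=tr)


def _fig6_induction(cfg: ExperimentConfig) -> ExperimentResult:
    p = cfg.get("params", default_parameters())
    n_def = cfg.get("n_default", 4)
    n_low = cfg.get("n_low", 16)
    gfactor = cfg.get("g_factor", 0.5)
    jit = cfg.get("jitter", 0.0)
    t_on = cfg.get("coupling_on_s", 6 * 3600.0)
    post = cfg.get("post_s", 8 * 3600.0)
    Ds = cfg.get("coupling_strengths", [0.5])
    n = n_def + n_low
    low_idx = list(range(n_def, n))
    rows, tabs = [], {}
    tr_keep = None
    for D in Ds:
        spec = NetworkSpec(
            n_cells=n, base_params=p, rate_jitter=jit, initial_jitter=jit,
            seed=cfg.seed,
            subgroups=((low_idx, {"g_CNG0": p.g_CNG0 * gfactor}),),
            coupling_schedule=((0.0, 0.0), (t_on, D)))
        net = build_network(spec)
        tr = simulate_network(net, t_on + post,
                              dt_out=cfg.get("dt_out", 30.0),
                              rtol=cfg.get("rtol", 1e-6))
        pre = _ensemble_stats(tr, 0.3 * t_on, t_on)
        post_tbl = _ensemble_stats(tr, t_on + 0.3 * post, t_on + post)
        F = tr.firing_rates
        try:
            ph, T = burst_phases(tr.t, F.T, t_start=t_on + 0.5 * post,
                                 t_stop=t_on + post)
            sd_s = phase_sd(ph, T)
        except (InsufficientDataError, ValueError):
            sd_s, T = np.nan, np.nan
        oscp = post_tbl[post_tbl.oscillating]
        rows.append(dict(
            D=D, n_osc_pre=int(pre.oscillating.sum()),
            n_osc_post=int(post_tbl.oscillating.sum()),
            period_post_mean_min=float(oscp.period_min.mean()),
            period_post_sd_min=float(oscp.period_min.std()),
            amplitude_post_mean_hz=float(oscp.amplitude_hz.mean()),
            amplitude_post_sd_hz=float(oscp.amplitude_hz.std()),
            phase_sd_post_s=float(sd_s)))
        tabs[f"post_D{D:g}"] = post_tbl
        if D == Ds[0]:
            tr_keep = tr
    table = pd.DataFrame(rows)
    first = table.iloc[0].to_dict()
    metrics = dict(first, coupling_series=table.to_dict("records"))
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides, metrics,
                            {"coupling_series": table, **tabs},
                            trajectory=tr_keep)


def _circadian_phase_sd(tr: NetworkTrajectory, series: str,
                        t0: float, t1: float) -> float:
    """Phase SD (h) of circadian activity between t0 and t1 (one window
    per 24 h)."""
    if series == "firing":
        A = tr.firing_rates.T
    else:
        A = tr.species(series).T
    sel = (tr.t >= t0) & (tr.t <= t1)
    ph = analysis.compute_phases(tr.t[sel], A[:, sel], window=24 * 3600.0)
    if ph.size == 0:
        return float("nan")
    return float(np.nanmean([phase_sd(row, 24 * 3600.0) / 3600.0
                             for row in ph if np.isfinite(row).sum() >= 2]))


def _fig7_circadian(cfg: ExperimentConfig) -> ExperimentResult:
    variant = cfg.get("variant", "vip_cng_with_fofr")
    series = cfg.get("series", 1)
    p0 = cfg.get("params", default_parameters())
    params, totals, vcfg = configure_variant(variant, p0)
    n = cfg.get("n_cells", 10)
    rng = np.random.default_rng(cfg.seed)
    t_on = cfg.get("coupling_on_s", 91 * 3600.0)
    D = cfg.get("D", 0.5)
    if series == 1:
        shifts = cfg.get("phase_shift_mode", "random")
        span = cfg.get("phase_span_h", 6.0)
        if shifts == "random":
            sh = rng.uniform(0.0, span, n)
        else:
            sh = np.linspace(0.0, span, n)
        spec = NetworkSpec(
            n_cells=n, base_params=params, totals=totals, seed=cfg.seed,
            coupling_schedule=((0.0, 0.0), (t_on, D)),
            with_clock=True, clock_phase_shifts_h=sh)
        duration = t_on + cfg.get("post_s", 72 * 3600.0)
    else:
        t_off = cfg.get("coupling_off_s", 403 * 3600.0)
        spec = NetworkSpec(
            n_cells=n, base_params=params, totals=totals, seed=cfg.seed,
            coupling_schedule=((0.0, 0.0), (t_on, D), (t_off, 0.0)),
            with_clock=True, clock_jitter=cfg.get("clock_jitter", 0.035))
        duration = t_off + cfg.get("post_off_s", 24 * 3600.0)
    net = build_network(spec)
    tr = simulate_network(net, duration, dt_out=cfg.get("dt_out", 120.0),
                          rtol=cfg.get("rtol", 1e-6))

    day = 24 * 3600.0
    metrics = dict(variant=variant, series=series)
    if series == 1:
        pre = (max(t_on - 2 * day, 0.0), t_on)
        just_after = (t_on, min(t_on + day, duration))
        late = (max(duration - 2 * day, t_on), duration)
        for name, ser in (("firing", "firing"), ("per", "MP")):
            metrics[f"{name}_phase_sd_pre_h"] = _circadian_phase_sd(
                tr, ser, *pre)
            metrics[f"{name}_phase_sd_post24_h"] = _circadian_phase_sd(
                tr, ser, *just_after)
            metrics[f"{name}_phase_sd_late_h"] = _circadian_phase_sd(
                tr, ser, *late)
    else:
        t_off = spec.coupling_schedule[2][0]
        before = (max(t_off - 2 * day, 0.0), t_off)
        after = (t_off, min(t_off + day, duration))
        for name, ser in (("firing", "firing"), ("per", "MP")):
            sd_b = _circadian_phase_sd(tr, ser, *before)
            sd_a = _circadian_phase_sd(tr, ser, *after)
            metrics[f"{name}_phase_sd_coupled_h"] = sd_b
            metrics[f"{name}_phase_sd_post_decoupling_h"] = sd_a
            metrics[f"{name}_decoupling_pct"] = (
                100.0 * sd_a / sd_b if sd_b and np.isfinite(sd_b) else
                float("nan"))
    return ExperimentResult(cfg.experiment, cfg.seed, cfg.overrides, metrics,
                            {}, trajectory=tr)


EXPERIMENTS = {
    "fig2_step": _fig2_step,
    "fig2_dose": _fig2_dose,
    "fig3_nullclines": _fig3_nullclines,
    "fig4_bifurcation": _fig4_bifurcation,
    "fig4_sensitivity": _fig4_sensitivity,
    "fig5_sync50": _fig5_sync50,
    "fig6_induction": _fig6_induction,
    "fig7_circadian": _fig7_circadian,
}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run one named experiment; saves the bundle when out_dir is set."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {config.experiment!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    t0 = time.time()
    result = EXPERIMENTS[config.experiment](config)
    result.wall_time_s = time.time() - t0
    if config.out_dir:
        result.save(config.out_dir)
    return result
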