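"""Per-cell circadian clock: the 16-variable mammalian transcription-
translation oscillator of Leloup & Goldbeter, coupled to the signalling
cascade through PKA/CREB-dependent Per transcription.

State variables (concentrations in nM, time in hours in the published
parameterization; this module converts to seconds at the coupling surface):

==== ===========================================================
MP   Per mRNA
MC   Cry mRNA
MB   Bmal1 mRNA
PC   PER protein, cytosolic
CC   CRY protein, cytosolic
PCP  phospho-PER, cytosolic
CCP  phospho-CRY, cytosolic
PCC  PER-CRY complex, cytosolic
PCN  PER-CRY complex, nuclear
PCCP phospho PER-CRY, cytosolic
PCNP phospho PER-CRY, nuclear
BC   BMAL1, cytosolic
BCP  phospho-BMAL1, cytosolic
BN   BMAL1, nuclear
BNP  phospho-BMAL1, nuclear
IN   inactive BN : PCN complex
==== ===========================================================

The coupling adds a CREB-driven term to Per transcription:
``dMP/dt += v_creb * a_CREB`` with ``a_CREB`` the saturating CREB activity
in [0, 1] computed from nuclear PKA.  With ``a_CREB = 0`` the system is
exactly the published autonomous clock.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CLOCK_SPECIES", "N_CLOCK", "ClockParameters", "clock_rhs",
    "creb_activity_from_pka", "limit_cycle_state", "free_running_period",
    "VARIANTS", "configure_variant", "VariantConfig",
]

CLOCK_SPECIES = ["MP", "MC", "MB", "PC", "CC", "PCP", "CCP", "PCC",
                 "PCN", "PCCP", "PCNP", "BC", "BCP", "BN", "BNP", "IN"]
N_CLOCK = len(CLOCK_SPECIES)
CIDX = {n: i for i, n in enumerate(CLOCK_SPECIES)}


@dataclass
class ClockParameters:
    """Basal parameter regime of the published mammalian clock model.

    Rates in nM/h or 1/h; the free-running period is close to 23.8 h.
    """
    k1: float = 0.4
    k2: float = 0.2
    k3: float = 0.4
    k4: float = 0.2
    k5: float = 0.4
    k6: float = 0.2
    k7: float = 0.5
    k8: float = 0.1
    KAP: float = 0.7
    KAC: float = 0.6
    KIB: float = 2.2
    kdmb: float = 0.01
    kdmc: float = 0.01
    kdmp: float = 0.01
    kdn: float = 0.01
    kdnc: float = 0.12
    Kd: float = 0.3
    Kdp: float = 0.1
    Kp: float = 0.1
    KmB: float = 0.4
    KmC: float = 0.4
    KmP: float = 0.31
    ksB: float = 0.12
    ksC: float = 1.6
    ksP: float = 0.6
    m: float = 2.0
    n: float = 4.0
    V1B: float = 0.5
    V1C: float = 0.6
    V1P: float = 0.4
    V1PC: float = 0.4
    V2B: float = 0.1
    V2C: float = 0.1
    V2P: float = 0.3
    V2PC: float = 0.1
    V3B: float = 0.5
    V3PC: float = 0.4
    V4B: float = 0.2
    V4PC: float = 0.1
    vdBC: float = 0.5
    vdBN: float = 0.6
    vdCC: float = 0.7
    vdIN: float = 0.8
    vdPC: float = 0.7
    vdPCC: float = 0.7
    vdPCN: float = 0.7
    vmB: float = 0.8
    vmC: float = 1.0
    vmP: float = 1.1
    vsB: float = 1.0
    vsC: float = 1.1
    vsP: float = 1.5
    # coupling: CREB-driven Per transcription (nM/h at full CREB activity)
    v_creb: float = 0.8
    K_pkan: float = 0.6   # nuclear-PKA half-activation of CREB drive (nM)

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name)
                         for f in dataclasses.fields(self)], dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ClockParameters":
        names = [f.name for f in dataclasses.fields(cls)]
        return cls(**{n: float(v[i]) for i, n in enumerate(names)})

    def replace(self, **kw) -> "ClockParameters":
        return dataclasses.replace(self, **kw)


CLOCK_PARAM_NAMES = [f.name for f in dataclasses.fields(ClockParameters)]
CPIDX = {n: i for i, n in enumerate(CLOCK_PARAM_NAMES)}
N_CLOCK_PARAMS = len(CLOCK_PARAM_NAMES)


def creb_activity_from_pka(nuclear_pka, K_pkan: float = 0.6) -> np.ndarray:
    """Saturating CREB transcriptional activity in [0, 1] from nuclear PKA."""
    x = np.asarray(nuclear_pka, dtype=float)
    if np.any(x < 0):
        raise ValueError("nuclear PKA must be >= 0")
    return x / (x + K_pkan)


def clock_rhs(c: np.ndarray, CP: np.ndarray, creb_activity=0.0) -> np.ndarray:
    """Clock derivatives in nM/h.  ``c`` is (..., 16); ``CP`` (..., nparams).

    With ``creb_activity`` > 0 the Per transcription term gains the
    additive CREB-dependent drive; 0 reduces exactly to the autonomous
    published model.
    """
    g = lambda n: CP[..., CPIDX[n]]
    MP = c[..., 0]; MC = c[..., 1]; MB = c[..., 2]
    PC = c[..., 3]; CC = c[..., 4]; PCP = c[..., 5]; CCP = c[..., 6]
    PCC = c[..., 7]; PCN = c[..., 8]; PCCP = c[..., 9]; PCNP = c[..., 10]
    BC = c[..., 11]; BCP = c[..., 12]; BN = c[..., 13]; BNP = c[..., 14]
    IN = c[..., 15]

    n = g("n"); m = g("m")
    dc = np.empty(np.broadcast_shapes(c.shape, CP.shape[:-1] + (N_CLOCK,)))
    dc[..., 0] = (g("vsP") * BN ** n / (g("KAP") ** n + BN ** n)
                  + g("v_creb") * np.asarray(creb_activity, float)
                  - g("vmP") * MP / (g("KmP") + MP) - g("kdmp") * MP)
    dc[..., 1] = (g("vsC") * BN ** n / (g("KAC") ** n + BN ** n)
                  - g("vmC") * MC / (g("KmC") + MC) - g("kdmc") * MC)
    dc[..., 2] = (g("vsB") * g("KIB") ** m / (g("KIB") ** m + BN ** m)
                  - g("vmB") * MB / (g("KmB") + MB) - g("kdmb") * MB)
    dc[..., 3] = (g("ksP") * MP - g("V1P") * PC / (g("Kp") + PC)
                  + g("V2P") * PCP / (g("Kdp") + PCP)
                  + g("k4") * PCC - g("k3") * PC * CC - g("kdn") * PC)
    dc[..., 4] = (g("ksC") * MC - g("V1C") * CC / (g("Kp") + CC)
                  + g("V2C") * CCP / (g("Kdp") + CCP)
                  + g("k4") * PCC - g("k3") * PC * CC - g("kdnc") * CC)
    dc[..., 5] = (g("V1P") * PC / (g("Kp") + PC)
                  - g("V2P") * PCP / (g("Kdp") + PCP)
                  - g("vdPC") * PCP / (g("Kd") + PCP) - g("kdn") * PCP)
    dc[..., 6] = (g("V1C") * CC / (g("Kp") + CC)
                  - g("V2C") * CCP / (g("Kdp") + CCP)
                  - g("vdCC") * CCP / (g("Kd") + CCP) - g("kdn") * CCP)
    dc[..., 7] = (-g("V1PC") * PCC / (g("Kp") + PCC)
                  + g("V2PC") * PCCP / (g("Kdp") + PCCP)
                  - g("k4") * PCC + g("k3") * PC * CC
                  + g("k2") * PCN - g("k1") * PCC - g("kdn") * PCC)
    dc[..., 8] = (-g("V3PC") * PCN / (g("Kp") + PCN)
                  + g("V4PC") * PCNP / (g("Kdp") + PCNP)
                  - g("k2") * PCN + g("k1") * PCC
                  - g("k7") * BN * PCN + g("k8") * IN - g("kdn") * PCN)
    dc[..., 9] = (g("V1PC") * PCC / (g("Kp") + PCC)
                  - g("V2PC") * PCCP / (g("Kdp") + PCCP)
                  - g("vdPCC") * PCCP / (g("Kd") + PCCP) - g("kdn") * PCCP)
    dc[..., 10] = (g("V3PC") * PCN / (g("Kp") + PCN)
                   - g("V4PC") * PCNP / (g("Kdp") + PCNP)
                   - g("vdPCN") * PCNP / (g("Kd") + PCNP) - g("kdn") * PCNP)
    dc[..., 11] = (g("ksB") * MB - g("V1B") * BC / (g("Kp") + BC)
                   + g("V2B") * BCP / (g("Kdp") + BCP)
                   - g("k5") * BC + g("k6") * BN - g("kdn") * BC)
    dc[..., 12] = (g("V1B") * BC / (g("Kp") + BC)
                   - g("V2B") * BCP / (g("Kdp") + BCP)
                   - g("vdBC") * BCP / (g("Kd") + BCP) - g("kdn") * BCP)
    dc[..., 13] = (-g("V3B") * BN / (g("Kp") + BN)
                   + g("V4B") * BNP / (g("Kdp") + BNP)
                   + g("k5") * BC - g("k6") * BN
                   - g("k7") * BN * PCN + g("k8") * IN - g("kdn") * BN)
    dc[..., 14] = (g("V3B") * BN / (g("Kp") + BN)
                   - g("V4B") * BNP / (g("Kdp") + BNP)
                   - g("vdBN") * BNP / (g("Kd") + BNP) - g("kdn") * BNP)
    dc[..., 15] = (-g("k8") * IN + g("k7") * BN * PCN
                   - g("vdIN") * IN / (g("Kd") + IN) - g("kdn") * IN)
    return dc


_GENERIC_INIT = np.array([
    2.0, 2.0, 8.0, 0.4, 12.0, 0.1, 9.0, 1.26,
    0.16, 0.2, 0.091, 2.41, 0.48, 1.94, 0.32, 0.05])


def limit_cycle_state(params: ClockParameters | None = None, *,
                      settle_days: float = 30.0) -> np.ndarray:
    """A point on the free-running limit cycle (at the Per-mRNA maximum)."""
    from scipy.integrate import solve_ivp
    params = params or ClockParameters()
    CP = params.vector()
    sol = solve_ivp(lambda t, c: clock_rhs(c, CP),
                    (0.0, settle_days * 24.0), _GENERIC_INIT,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    c = sol.y[:, -1]
    # advance to the next MP maximum so phase-zero is reproducible
    sol2 = solve_ivp(lambda t, cc: clock_rhs(cc, CP), (0.0, 30.0), c,
                     method="LSODA", rtol=1e-9, atol=1e-11, max_step=0.05)
    mp = sol2.y[0]
    i = int(np.argmax(mp))
    return sol2.y[:, i]


def free_running_period(params: ClockParameters | None = None, *,
                        n_cycles: int = 10) -> float:
    """Free-running period (h) from successive Per-mRNA maxima."""
    from scipy.integrate import solve_ivp
    from scipy.signal import find_peaks
    params = params or ClockParameters()
    CP = params.vector()
    c0 = limit_cycle_state(params)
    T = (n_cycles + 1) * 25.0
    t_eval = np.arange(0.0, T, 0.02)
    sol = solve_ivp(lambda t, c: clock_rhs(c, CP), (0.0, T), c0,
                    method="LSODA", rtol=1e-9, atol=1e-11, t_eval=t_eval)
    mp = sol.y[0]
    pk, _ = find_peaks(mp, prominence=0.1 * (mp.max() - mp.min()))
    if pk.size < 3:
        raise RuntimeError("clock did not sustain oscillations")
    return float(np.diff(sol.t[pk]).mean())


# ---------------------------------------------------------------------------
# circadian-regulation variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantConfig:
    """One of the three circadian-regulation model variants.

    * ``no_vip_cng`` — firing driven solely by the Per product
      (per-independent CNG fraction 1.0); the cAMP branch of CNG is absent.
    * ``vip_cng_with_fofr`` — 80% of CNG channels follow cAMP (fast VIP
      loop intact, FOFR present), 20% follow Per.
    * ``vip_cng_without_fofr`` — 10% of CNG follows Per, receptor
      desensitization removed (GRK pool emptied) so FOFR cannot ignite;
      remaining overrides hold the cell near the monostable/bistable
      transition so paracrine VIP can still steer firing.
    """
    variant_id: str
    per_independent_fraction: float
    grk_total: float | None = None          # None: default pool
    cell_overrides: tuple = ()               # ((name, value), ...)


VARIANTS: dict[str, VariantConfig] = {
    # Per product is the sole CNG driver; half-activation placed inside the
    # Per-mRNA excursion so firing tracks the circadian cycle
    "no_vip_cng": VariantConfig("no_vip_cng", 1.0,
                                cell_overrides=(("K_per", 6.0),)),
    # 80% of CNG follows cAMP (FOFR machinery intact); the 20% Per-coupled
    # fraction biases excitability without leaving the oscillatory regime
    "vip_cng_with_fofr": VariantConfig("vip_cng_with_fofr", 0.2,
                                       cell_overrides=(("K_per", 30.0),)),
    # desensitization removed (GRK pool emptied); CNG conductance reduced to
    # the value located by a scripted scan just above the silent/firing fold,
    # so VIP and Per inputs modulate firing without igniting FOFR
    "vip_cng_without_fofr": VariantConfig(
        "vip_cng_without_fofr", 0.1, grk_total=0.0,
        cell_overrides=(("K_per", 4.0), ("g_CNG0", 0.2))),
}


def configure_variant(variant_id: str, base):
    """(CellParameters, totals overrides, VariantConfig) for a variant."""
    if variant_id not in VARIANTS:
        raise ValueError(f"unknown variant {variant_id!r}; "
                         f"choose from {sorted(VARIANTS)}")
    cfg = VARIANTS[variant_id]
    params = base.replace(
        per_independent_fraction=cfg.per_independent_fraction,
        **dict(cfg.cell_overrides))
    totals = {"GRK": cfg.grk_total} if cfg.grk_total is not None else None
    return params, totals, cfg
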