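"""Right-hand side of the single-cell signalling model.

The network couples five mass-action modules:

1. VIP binding to surface VPAC2 receptors (plain and Gs-precoupled, in both
   phosphorylation states);
2. the Gs cycle: ternary-complex GDP/GTP exchange, hydrolysis and
   heterotrimer reassociation;
3. adenylate cyclase: Galpha_s-GTP binding, ATP turnover (plus a small
   Gs-independent basal activity) and cAMP degradation by a
   phosphodiesterase that PKA itself activates (fast negative feedback);
4. PKA activation by sequential binding of four cAMP molecules to the
   holoenzyme, release of catalytic subunits, buffering by a cytoplasmic
   inhibitor and nuclear shuttling;
5. the slow negative feedback: PKA phosphorylates GRK, active GRK
   phosphorylates VIP-occupied receptors, phosphorylated receptors couple
   weakly to Gs (factor ``DE``), internalize (``k_42``) and recycle slowly
   (``k_70``) — the loop that terminates each firing burst and sets the
   interburst interval.

Membrane electricity is reduced to algebra: CNG conductance follows cAMP
(and optionally the Per gene product) through saturating Hill functions, and
the firing rate is a thresholded, saturating function of CNG current.  VIP
secretion is proportional to the firing rate, closing the autocrine loop.

Everything is vectorized: ``y`` may be shaped ``(47,)`` or ``(n_cells, 47)``
with per-cell parameter arrays, so the same code serves the single cell and
the coupled network.
"""

from __future__ import annotations

import numpy as np

from .params import PIDX
from .species import IDX, N_SPECIES

__all__ = [
    "rhs", "cng_conductance", "firing_rate_from_current", "cng_current",
    "firing_rate", "vip_release_rate", "assemble_resting_state",
]

_I = IDX  # local alias


def _p(P: np.ndarray, name: str) -> np.ndarray:
    return P[..., PIDX[name]]


def cng_conductance(camp, per_product, P) -> np.ndarray:
    """CNG conductance for given cAMP (nM) and Per gene product.

    g = g_CNG0 * [(1 - f) * h(cAMP) + f * h_per(Per)] with saturating Hill
    activations; ``f`` is the fraction of CNG channels that are independent
    of local cAMP (driven by the circadian Per product instead).
    """
    camp = np.asarray(camp, dtype=float)
    f = _p(P, "per_independent_fraction")
    hc = camp ** _p(P, "n_CNG") / (
        camp ** _p(P, "n_CNG") + _p(P, "K_CNG") ** _p(P, "n_CNG"))
    if np.ndim(per_product) == 0 and per_product == 0:
        hp = 0.0
    else:
        per = np.asarray(per_product, dtype=float)
        hp = per ** _p(P, "n_per") / (
            per ** _p(P, "n_per") + _p(P, "K_per") ** _p(P, "n_per"))
    return _p(P, "g_CNG0") * ((1.0 - f) * hc + f * hp)


def firing_rate_from_current(current, P) -> np.ndarray:
    """Piecewise-linear, saturating current -> firing-rate transfer.

    Zero below ``I_threshold``, linear up to ``I_sat``, flat at ``F_max``.
    """
    i_th = _p(P, "I_threshold")
    i_sat = _p(P, "I_sat")
    x = (np.asarray(current, dtype=float) - i_th) / (i_sat - i_th)
    return _p(P, "F_max") * np.clip(x, 0.0, 1.0)


def cng_current(y, P, per_product=0.0) -> np.ndarray:
    """CNG current (conductance units; unit driving force)."""
    return cng_conductance(y[..., _I["cAMP"]], per_product, P)


def firing_rate(y, P, per_product=0.0) -> np.ndarray:
    return firing_rate_from_current(cng_current(y, P, per_product), P)


def vip_release_rate(rate_hz, P) -> np.ndarray:
    """VIP secretion flux (nM/s) into the perimembrane pool."""
    return _p(P, "k_sec") * np.asarray(rate_hz, dtype=float)


def rhs(y: np.ndarray, P: np.ndarray, *, vip_clamped: bool = False,
        secretion_on: bool = True, per_product=0.0,
        extra_dL=None) -> np.ndarray:
    """Time derivatives (nM/s) of the 47-species state.

    Parameters
    ----------
    y : (..., 47) state
    P : (..., n_params) parameter vectors (broadcast against y)
    vip_clamped : freeze free VIP (bath-application protocols)
    secretion_on : include firing-rate-dependent VIP secretion
    per_product : Per gene product driving the clock-coupled CNG fraction
    extra_dL : additional dL/dt term (network exchange flux), broadcastable
    """
    g = lambda n: P[..., PIDX[n]]

    L = y[..., 0]
    R = y[..., 1]
    LR = y[..., 2]
    Rp = y[..., 3]
    LRp = y[..., 4]
    RGs = y[..., 5]
    LRGs = y[..., 6]
    LRpGs = y[..., 7]
    RpGs = y[..., 8]
    Rint = y[..., 9]
    Rintp = y[..., 10]
    Gs = y[..., 11]
    GaGTP = y[..., 12]
    GaGDP = y[..., 13]
    Gbg = y[..., 14]
    AC = y[..., 15]
    GaAC = y[..., 16]
    GaACATP = y[..., 17]
    ACATP = y[..., 18]
    ATP = y[..., 19]
    cAMP = y[..., 20]
    AMP = y[..., 21]
    PDE = y[..., 22]
    PDEcAMP = y[..., 23]
    PDEp = y[..., 24]
    PDEpcAMP = y[..., 25]
    PKACPDE = y[..., 26]
    R2C2 = y[..., 27]
    R2C2c1 = y[..., 28]
    R2C2c2 = y[..., 29]
    R2C2c3 = y[..., 30]
    R2C2c4 = y[..., 31]
    R2Cc4 = y[..., 32]
    R2c4 = y[..., 33]
    R2 = y[..., 34]
    R2C = y[..., 35]
    PKAC = y[..., 36]
    PKI = y[..., 37]
    PKIPKAC = y[..., 38]
    PKAn = y[..., 39]
    GRK = y[..., 40]
    PKACGRK = y[..., 41]
    GRKp = y[..., 42]
    GRKpLR = y[..., 43]
    CREB = y[..., 44]
    PKAnCREB = y[..., 45]
    CREBa = y[..., 46]

    kon_L = g("kon_L")
    koff_L = g("koff_L")
    koff_LG = g("koff_LG")
    kon_g_r = g("kon_g_r")
    kon_g_lr = g("kon_g_lr")
    koff_g = g("koff_g")
    DE = g("DE")

    # ligand binding (free VIP treated as an unloaded bath)
    b1f = kon_L * L * R;     b1r = koff_L * LR
    b2f = kon_L * L * Rp;    b2r = koff_L * LRp
    b3f = kon_L * L * RGs;   b3r = koff_LG * LRGs
    b4f = kon_L * L * RpGs;  b4r = koff_LG * LRpGs

    # Gs association
    g1f = kon_g_r * R * Gs;        g1r = koff_g * RGs
    g2f = kon_g_lr * LR * Gs;      g2r = koff_g * LRGs
    g3f = DE * kon_g_r * Rp * Gs;  g3r = koff_g * RpGs
    g4f = DE * kon_g_lr * LRp * Gs; g4r = koff_g * LRpGs

    # GDP/GTP exchange (agonist and constitutive)
    a1 = g("kact") * LRGs
    a2 = g("kact") * LRpGs
    a3 = g("kact0") * RGs
    a4 = g("kact0") * RpGs

    h1 = g("khyd") * GaGTP
    re = g("krea") * GaGDP * Gbg

    # adenylate cyclase
    c1f = g("kon_ac") * GaGTP * AC; c1r = g("koff_ac") * GaAC
    h2 = g("khyd_ac") * GaAC
    t1f = g("kon_atp") * GaAC * ATP; t1r = g("koff_atp") * GaACATP
    cat1 = g("kcat_ac") * GaACATP
    t2f = g("kon_atp_b") * AC * ATP; t2r = g("koff_atp_b") * ACATP
    cat2 = g("kcat_ac_b") * ACATP

    # phosphodiesterase
    d1f = g("kon_pde") * PDE * cAMP;   d1r = g("koff_pde") * PDEcAMP
    dcat1 = g("kcat_pde") * PDEcAMP
    d2f = g("kon_pde") * PDEp * cAMP;  d2r = g("koff_pde") * PDEpcAMP
    dcat2 = g("kcat_pdep") * PDEpcAMP
    e1f = g("kon_kpde") * PKAC * PDE;  e1r = g("koff_kpde") * PKACPDE
    ecat = g("kcat_kpde") * PKACPDE
    dp = g("kdeph_pde") * PDEp
    recyc = g("k_amp") * AMP

    # PKA: sequential cAMP binding and catalytic-subunit release
    kon_pka = g("kon_pka")
    p1f = kon_pka * R2C2 * cAMP;   p1r = g("koff_pka1") * R2C2c1
    p2f = kon_pka * R2C2c1 * cAMP; p2r = g("koff_pka2") * R2C2c2
    p3f = kon_pka * R2C2c2 * cAMP; p3r = g("koff_pka3") * R2C2c3
    p4f = kon_pka * R2C2c3 * cAMP; p4r = g("koff_pka4") * R2C2c4
    rel1f = g("krel1") * R2C2c4;   rel1r = g("krb1") * R2Cc4 * PKAC
    rel2f = g("krel2") * R2Cc4;    rel2r = g("krb2") * R2c4 * PKAC
    reln = g("kreln") * R2c4
    asm1f = g("kasm") * R2 * PKAC;  asm1r = g("kdis0") * R2C
    asm2f = g("kasm2") * R2C * PKAC; asm2r = g("kdis0") * R2C2
    ki_f = g("kon_pki") * PKI * PKAC; ki_r = g("koff_pki") * PKIPKAC
    nin = g("kin_n") * PKAC;       nout = g("kout_n") * PKAn

    # GRK activation and receptor phosphorylation
    gk1f = g("kon_grk") * PKAC * GRK; gk1r = g("koff_grk") * PKACGRK
    gk1c = g("k_61") * PKACGRK
    gk2 = g("k_62") * GRKp
    gr1f = g("kon_grkr") * GRKp * LR; gr1r = g("koff_grkr") * GRKpLR
    gr1c = g("k_63") * GRKpLR
    deph_s1 = g("k_64") * Rp
    deph_s2 = g("k_64") * LRp

    # internalization / recycling
    int1 = g("k_42") * Rp
    int2 = g("k_42") * LRp
    deph_i = g("k_deph_int") * Rintp
    rec = g("k_70") * Rint

    # CREB
    cr1f = g("kon_creb") * PKAn * CREB; cr1r = g("koff_creb") * PKAnCREB
    cr1c = g("kcat_creb") * PKAnCREB
    crd = g("k_crebd") * CREBa

    dy = np.empty(np.broadcast_shapes(y.shape, P.shape[:-1] + (N_SPECIES,)),
                  dtype=float)

    # free VIP
    if vip_clamped:
        dL = np.zeros_like(L)
    else:
        F = firing_rate(y, P, per_product)
        dL = g("k_L") * (g("VIP_0") - L)
        if secretion_on:
            dL = dL + g("k_sec") * F
        if extra_dL is not None:
            dL = dL + extra_dL
    dy[..., 0] = dL

    dy[..., 1] = -b1f + b1r - g1f + g1r + a3 + deph_s1 + rec
    dy[..., 2] = b1f - b1r - g2f + g2r + a1 + deph_s2 - gr1f + gr1r
    dy[..., 3] = -b2f + b2r - g3f + g3r + a4 - deph_s1 - int1
    dy[..., 4] = b2f - b2r - g4f + g4r + a2 + gr1c - deph_s2 - int2
    dy[..., 5] = g1f - g1r - b3f + b3r - a3
    dy[..., 6] = g2f - g2r + b3f - b3r - a1
    dy[..., 7] = g4f - g4r + b4f - b4r - a2
    dy[..., 8] = g3f - g3r - b4f + b4r - a4
    dy[..., 9] = deph_i - rec
    dy[..., 10] = int1 + int2 - deph_i
    dy[..., 11] = -(g1f + g2f + g3f + g4f) + (g1r + g2r + g3r + g4r) + re
    dy[..., 12] = a1 + a2 + a3 + a4 - h1 - c1f + c1r
    dy[..., 13] = h1 + h2 - re
    dy[..., 14] = a1 + a2 + a3 + a4 - re
    dy[..., 15] = -c1f + c1r + h2 - t2f + t2r + cat2
    dy[..., 16] = c1f - c1r - h2 - t1f + t1r + cat1
    dy[..., 17] = t1f - t1r - cat1
    dy[..., 18] = t2f - t2r - cat2
    atp_free = -t1f + t1r - t2f + t2r + recyc
    dy[..., 19] = np.where(g("atp_clamped") > 0.5, 0.0, atp_free)
    dy[..., 20] = (cat1 + cat2 - d1f + d1r - d2f + d2r
                   - (p1f + p2f + p3f + p4f) + (p1r + p2r + p3r + p4r)
                   + 4.0 * reln)
    dy[..., 21] = dcat1 + dcat2 - recyc
    dy[..., 22] = -d1f + d1r + dcat1 - e1f + e1r + dp
    dy[..., 23] = d1f - d1r - dcat1
    dy[..., 24] = -d2f + d2r + dcat2 + ecat - dp
    dy[..., 25] = d2f - d2r - dcat2
    dy[..., 26] = e1f - e1r - ecat
    dy[..., 27] = -p1f + p1r + asm2f - asm2r
    dy[..., 28] = p1f - p1r - p2f + p2r
    dy[..., 29] = p2f - p2r - p3f + p3r
    dy[..., 30] = p3f - p3r - p4f + p4r
    dy[..., 31] = p4f - p4r - rel1f + rel1r
    dy[..., 32] = rel1f - rel1r - rel2f + rel2r
    dy[..., 33] = rel2f - rel2r - reln
    dy[..., 34] = reln - asm1f + asm1r
    dy[..., 35] = asm1f - asm1r - asm2f + asm2r
    dy[..., 36] = (rel1f - rel1r + rel2f - rel2r - asm1f + asm1r
                   - asm2f + asm2r - ki_f + ki_r - nin + nout
                   - gk1f + gk1r + gk1c - e1f + e1r + ecat)
    dy[..., 37] = -ki_f + ki_r
    dy[..., 38] = ki_f - ki_r
    dy[..., 39] = nin - nout - cr1f + cr1r + cr1c
    dy[..., 40] = -gk1f + gk1r + gk2
    dy[..., 41] = gk1f - gk1r - gk1c
    dy[..., 42] = gk1c - gk2 - gr1f + gr1r + gr1c
    dy[..., 43] = gr1f - gr1r - gr1c
    dy[..., 44] = -cr1f + cr1r + crd
    dy[..., 45] = cr1f - cr1r - cr1c
    dy[..., 46] = cr1c - crd
    return dy


def make_rhs(P: np.ndarray, *, vip_clamped: bool = False,
             secretion_on: bool = True, per_product: float = 0.0):
    """Fastest available f(t, y) closure for one cell (compiled kernel when
    numba is present, numpy otherwise)."""
    from . import _kernel
    if _kernel.HAVE_NUMBA:
        def f(t, y, _P=P, _c=vip_clamped, _s=secretion_on, _pp=per_product):
            return _kernel.cell_rhs_single(y, _P, _c, _s, _pp)
        return f

    def f(t, y, _P=P, _c=vip_clamped, _s=secretion_on, _pp=per_product):
        return rhs(y, _P, vip_clamped=_c, secretion_on=_s, per_product=_pp)
    return f


#: canonical initial concentrations (nM) of a resting cell: the molecular
#: pools a cell is assembled from, including the physiologically precoupled
#: complexes (receptor:Gs, the PKA reassembly intermediate R2C, free
#: G-betagamma); every other complex starts empty and fills during the
#: relaxation transient.  These are the quantities the global sensitivity
#: scan varies.
DEFAULT_TOTALS = {
    "R": 250.0, "RGs": 50.0, "Gs": 950.0, "Gbg": 10.0,
    "AC": 100.0, "ATP": 2.0e6, "cAMP": 30.0, "PDE": 200.0,
    "R2C2": 395.0, "R2C": 10.0, "PKI": 50.0, "GRK": 150.0, "CREB": 100.0,
}


def assemble_resting_state(P: np.ndarray | None = None,
                           totals: dict[str, float] | None = None,
                           vip: float | None = None) -> np.ndarray:
    """The canonical initial-concentration vector (see DEFAULT_TOTALS)."""
    from .params import CellParameters
    if P is None:
        P = CellParameters().vector()
    y = np.zeros(N_SPECIES)
    t = dict(DEFAULT_TOTALS)
    if totals:
        t.update(totals)
    for name, v in t.items():
        y[IDX[name]] = v
    y[IDX["L"]] = _p(P, "VIP_0") if vip is None else vip
    return y


def initial_concentrations(params=None,
                           totals: dict[str, float] | None = None
                           ) -> np.ndarray:
    """Alias for the canonical initial state of one cell (47-vector)."""
    P = params.vector() if params is not None else None
    return assemble_resting_state(P, totals)
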