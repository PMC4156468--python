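"""Compiled fast path for the single-cell right-hand side.

This mirrors :func:`fofr.model.rhs` exactly (a regression test asserts
agreement to machine precision on random states); it exists because the
stiff solver evaluates the RHS tens of thousands of times per simulated
day.  When numba is unavailable the package silently falls back to the
numpy implementation.
"""

from __future__ import annotations

import numpy as np

from .params import PIDX

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


# parameter indices as module-level ints (frozen into the compiled kernel)
P_kon_L = PIDX["kon_L"]; P_koff_L = PIDX["koff_L"]; P_koff_LG = PIDX["koff_LG"]
P_kon_g_r = PIDX["kon_g_r"]; P_kon_g_lr = PIDX["kon_g_lr"]
P_koff_g = PIDX["koff_g"]; P_DE = PIDX["DE"]; P_kact = PIDX["kact"]
P_kact0 = PIDX["kact0"]; P_khyd = PIDX["khyd"]; P_krea = PIDX["krea"]
P_kon_ac = PIDX["kon_ac"]; P_koff_ac = PIDX["koff_ac"]
P_khyd_ac = PIDX["khyd_ac"]; P_kon_atp = PIDX["kon_atp"]
P_koff_atp = PIDX["koff_atp"]; P_kcat_ac = PIDX["kcat_ac"]
P_kon_atp_b = PIDX["kon_atp_b"]; P_koff_atp_b = PIDX["koff_atp_b"]
P_kcat_ac_b = PIDX["kcat_ac_b"]; P_kon_pde = PIDX["kon_pde"]
P_koff_pde = PIDX["koff_pde"]; P_kcat_pde = PIDX["kcat_pde"]
P_kcat_pdep = PIDX["kcat_pdep"]; P_kon_kpde = PIDX["kon_kpde"]
P_koff_kpde = PIDX["koff_kpde"]; P_kcat_kpde = PIDX["kcat_kpde"]
P_kdeph_pde = PIDX["kdeph_pde"]; P_k_amp = PIDX["k_amp"]
P_kon_pka = PIDX["kon_pka"]; P_koff_pka1 = PIDX["koff_pka1"]
P_koff_pka2 = PIDX["koff_pka2"]; P_koff_pka3 = PIDX["koff_pka3"]
P_koff_pka4 = PIDX["koff_pka4"]; P_krel1 = PIDX["krel1"]
P_krb1 = PIDX["krb1"]; P_krel2 = PIDX["krel2"]; P_krb2 = PIDX["krb2"]
P_kreln = PIDX["kreln"]; P_kasm = PIDX["kasm"]; P_kasm2 = PIDX["kasm2"]
P_kdis0 = PIDX["kdis0"]; P_kon_pki = PIDX["kon_pki"]
P_koff_pki = PIDX["koff_pki"]; P_kin_n = PIDX["kin_n"]
P_kout_n = PIDX["kout_n"]; P_kon_grk = PIDX["kon_grk"]
P_koff_grk = PIDX["koff_grk"]; P_k_61 = PIDX["k_61"]; P_k_62 = PIDX["k_62"]
P_kon_grkr = PIDX["kon_grkr"]; P_koff_grkr = PIDX["koff_grkr"]
P_k_63 = PIDX["k_63"]; P_k_64 = PIDX["k_64"]; P_k_42 = PIDX["k_42"]
P_k_deph_int = PIDX["k_deph_int"]; P_k_70 = PIDX["k_70"]
P_kon_creb = PIDX["kon_creb"]; P_koff_creb = PIDX["koff_creb"]
P_kcat_creb = PIDX["kcat_creb"]; P_k_crebd = PIDX["k_crebd"]
P_g_CNG0 = PIDX["g_CNG0"]; P_K_CNG = PIDX["K_CNG"]; P_n_CNG = PIDX["n_CNG"]
P_f_per = PIDX["per_independent_fraction"]; P_K_per = PIDX["K_per"]
P_n_per = PIDX["n_per"]; P_I_threshold = PIDX["I_threshold"]
P_I_sat = PIDX["I_sat"]; P_F_max = PIDX["F_max"]; P_VIP_0 = PIDX["VIP_0"]
P_k_L = PIDX["k_L"]; P_k_sec = PIDX["k_sec"]
P_atp_clamped = PIDX["atp_clamped"]


@njit(cache=True, fastmath=False)
def firing_rate_kernel(camp, per_product, P):
    f = P[P_f_per]
    hc = camp ** P[P_n_CNG] / (camp ** P[P_n_CNG] + P[P_K_CNG] ** P[P_n_CNG])
    if f > 0.0:
        hp = (per_product ** P[P_n_per]
              / (per_product ** P[P_n_per] + P[P_K_per] ** P[P_n_per]))
    else:
        hp = 0.0
    current = P[P_g_CNG0] * ((1.0 - f) * hc + f * hp)
    x = (current - P[P_I_threshold]) / (P[P_I_sat] - P[P_I_threshold])
    if x < 0.0:
        x = 0.0
    elif x > 1.0:
        x = 1.0
    return P[P_F_max] * x


@njit(cache=True, fastmath=False)
def cell_rhs_kernel(y, P, dy, vip_clamped, secretion_on, per_product,
                    extra_dL):
    L = y[0]; R = y[1]; LR = y[2]; Rp = y[3]; LRp = y[4]
    RGs = y[5]; LRGs = y[6]; LRpGs = y[7]; RpGs = y[8]
    Rint = y[9]; Rintp = y[10]; Gs = y[11]; GaGTP = y[12]; GaGDP = y[13]
    Gbg = y[14]; AC = y[15]; GaAC = y[16]; GaACATP = y[17]; ACATP = y[18]
    ATP = y[19]; cAMP = y[20]; AMP = y[21]; PDE = y[22]; PDEcAMP = y[23]
    PDEp = y[24]; PDEpcAMP = y[25]; PKACPDE = y[26]; R2C2 = y[27]
    R2C2c1 = y[28]; R2C2c2 = y[29]; R2C2c3 = y[30]; R2C2c4 = y[31]
    R2Cc4 = y[32]; R2c4 = y[33]; R2 = y[34]; R2C = y[35]; PKAC = y[36]
    PKI = y[37]; PKIPKAC = y[38]; PKAn = y[39]; GRK = y[40]
    PKACGRK = y[41]; GRKp = y[42]; GRKpLR = y[43]; CREB = y[44]
    PKAnCREB = y[45]; CREBa = y[46]

    b1f = P[P_kon_L] * L * R;     b1r = P[P_koff_L] * LR
    b2f = P[P_kon_L] * L * Rp;    b2r = P[P_koff_L] * LRp
    b3f = P[P_kon_L] * L * RGs;   b3r = P[P_koff_LG] * LRGs
    b4f = P[P_kon_L] * L * RpGs;  b4r = P[P_koff_LG] * LRpGs

    g1f = P[P_kon_g_r] * R * Gs;          g1r = P[P_koff_g] * RGs
    g2f = P[P_kon_g_lr] * LR * Gs;        g2r = P[P_koff_g] * LRGs
    g3f = P[P_DE] * P[P_kon_g_r] * Rp * Gs;   g3r = P[P_koff_g] * RpGs
    g4f = P[P_DE] * P[P_kon_g_lr] * LRp * Gs; g4r = P[P_koff_g] * LRpGs

    a1 = P[P_kact] * LRGs
    a2 = P[P_kact] * LRpGs
    a3 = P[P_kact0] * RGs
    a4 = P[P_kact0] * RpGs

    h1 = P[P_khyd] * GaGTP
    re = P[P_krea] * GaGDP * Gbg

    c1f = P[P_kon_ac] * GaGTP * AC; c1r = P[P_koff_ac] * GaAC
    h2 = P[P_khyd_ac] * GaAC
    t1f = P[P_kon_atp] * GaAC * ATP; t1r = P[P_koff_atp] * GaACATP
    cat1 = P[P_kcat_ac] * GaACATP
    t2f = P[P_kon_atp_b] * AC * ATP; t2r = P[P_koff_atp_b] * ACATP
    cat2 = P[P_kcat_ac_b] * ACATP

    d1f = P[P_kon_pde] * PDE * cAMP;   d1r = P[P_koff_pde] * PDEcAMP
    dcat1 = P[P_kcat_pde] * PDEcAMP
    d2f = P[P_kon_pde] * PDEp * cAMP;  d2r = P[P_koff_pde] * PDEpcAMP
    dcat2 = P[P_kcat_pdep] * PDEpcAMP
    e1f = P[P_kon_kpde] * PKAC * PDE;  e1r = P[P_koff_kpde] * PKACPDE
    ecat = P[P_kcat_kpde] * PKACPDE
    dp = P[P_kdeph_pde] * PDEp
    recyc = P[P_k_amp] * AMP

    p1f = P[P_kon_pka] * R2C2 * cAMP;   p1r = P[P_koff_pka1] * R2C2c1
    p2f = P[P_kon_pka] * R2C2c1 * cAMP; p2r = P[P_koff_pka2] * R2C2c2
    p3f = P[P_kon_pka] * R2C2c2 * cAMP; p3r = P[P_koff_pka3] * R2C2c3
    p4f = P[P_kon_pka] * R2C2c3 * cAMP; p4r = P[P_koff_pka4] * R2C2c4
    rel1f = P[P_krel1] * R2C2c4;   rel1r = P[P_krb1] * R2Cc4 * PKAC
    rel2f = P[P_krel2] * R2Cc4;    rel2r = P[P_krb2] * R2c4 * PKAC
    reln = P[P_kreln] * R2c4
    asm1f = P[P_kasm] * R2 * PKAC;   asm1r = P[P_kdis0] * R2C
    asm2f = P[P_kasm2] * R2C * PKAC; asm2r = P[P_kdis0] * R2C2
    ki_f = P[P_kon_pki] * PKI * PKAC; ki_r = P[P_koff_pki] * PKIPKAC
    nin = P[P_kin_n] * PKAC;       nout = P[P_kout_n] * PKAn

    gk1f = P[P_kon_grk] * PKAC * GRK; gk1r = P[P_koff_grk] * PKACGRK
    gk1c = P[P_k_61] * PKACGRK
    gk2 = P[P_k_62] * GRKp
    gr1f = P[P_kon_grkr] * GRKp * LR; gr1r = P[P_koff_grkr] * GRKpLR
    gr1c = P[P_k_63] * GRKpLR
    deph_s1 = P[P_k_64] * Rp
    deph_s2 = P[P_k_64] * LRp

    int1 = P[P_k_42] * Rp
    int2 = P[P_k_42] * LRp
    deph_i = P[P_k_deph_int] * Rintp
    rec = P[P_k_70] * Rint

    cr1f = P[P_kon_creb] * PKAn * CREB; cr1r = P[P_koff_creb] * PKAnCREB
    cr1c = P[P_kcat_creb] * PKAnCREB
    crd = P[P_k_crebd] * CREBa

    if vip_clamped:
        dy[0] = 0.0
    else:
        dL = P[P_k_L] * (P[P_VIP_0] - L) + extra_dL
        if secretion_on:
            dL += P[P_k_sec] * firing_rate_kernel(cAMP, per_product, P)
        dy[0] = dL

    dy[1] = -b1f + b1r - g1f + g1r + a3 + deph_s1 + rec
    dy[2] = b1f - b1r - g2f + g2r + a1 + deph_s2 - gr1f + gr1r
    dy[3] = -b2f + b2r - g3f + g3r + a4 - deph_s1 - int1
    dy[4] = b2f - b2r - g4f + g4r + a2 + gr1c - deph_s2 - int2
    dy[5] = g1f - g1r - b3f + b3r - a3
    dy[6] = g2f - g2r + b3f - b3r - a1
    dy[7] = g4f - g4r + b4f - b4r - a2
    dy[8] = g3f - g3r - b4f + b4r - a4
    dy[9] = deph_i - rec
    dy[10] = int1 + int2 - deph_i
    dy[11] = -(g1f + g2f + g3f + g4f) + (g1r + g2r + g3r + g4r) + re
    dy[12] = a1 + a2 + a3 + a4 - h1 - c1f + c1r
    dy[13] = h1 + h2 - re
    dy[14] = a1 + a2 + a3 + a4 - re
    dy[15] = -c1f + c1r + h2 - t2f + t2r + cat2
    dy[16] = c1f - c1r - h2 - t1f + t1r + cat1
    dy[17] = t1f - t1r - cat1
    dy[18] = t2f - t2r - cat2
    if P[P_atp_clamped] > 0.5:
        dy[19] = 0.0
    else:
        dy[19] = -t1f + t1r - t2f + t2r + recyc
    dy[20] = (cat1 + cat2 - d1f + d1r - d2f + d2r
              - (p1f + p2f + p3f + p4f) + (p1r + p2r + p3r + p4r)
              + 4.0 * reln)
    dy[21] = dcat1 + dcat2 - recyc
    dy[22] = -d1f + d1r + dcat1 - e1f + e1r + dp
    dy[23] = d1f - d1r - dcat1
    dy[24] = -d2f + d2r + dcat2 + ecat - dp
    dy[25] = d2f - d2r - dcat2
    dy[26] = e1f - e1r - ecat
    dy[27] = -p1f + p1r + asm2f - asm2r
    dy[28] = p1f - p1r - p2f + p2r
    dy[29] = p2f - p2r - p3f + p3r
    dy[30] = p3f - p3r - p4f + p4r
    dy[31] = p4f - p4r - rel1f + rel1r
    dy[32] = rel1f - rel1r - rel2f + rel2r
    dy[33] = rel2f - rel2r - reln
    dy[34] = reln - asm1f + asm1r
    dy[35] = asm1f - asm1r - asm2f + asm2r
    dy[36] = (rel1f - rel1r + rel2f - rel2r - asm1f + asm1r
              - asm2f + asm2r - ki_f + ki_r - nin + nout
              - gk1f + gk1r + gk1c - e1f + e1r + ecat)
    dy[37] = -ki_f + ki_r
    dy[38] = ki_f - ki_r
    dy[39] = nin - nout - cr1f + cr1r + cr1c
    dy[40] = -gk1f + gk1r + gk2
    dy[41] = gk1f - gk1r - gk1c
    dy[42] = gk1c - gk2 - gr1f + gr1r + gr1c
    dy[43] = gr1f - gr1r - gr1c
    dy[44] = -cr1f + cr1r + crd
    dy[45] = cr1f - cr1r - cr1c
    dy[46] = cr1c - crd
    return dy


@njit(cache=True, fastmath=False)
def cell_rhs_single(y, P, vip_clamped, secretion_on, per_product):
    dy = np.empty(47)
    cell_rhs_kernel(y, P, dy, vip_clamped, secretion_on, per_product, 0.0)
    return dy


@njit(cache=True, fastmath=False)
def network_rhs_batch(Y, Pmat, per_products, extra_dL):
    """Batched RHS: Y (n, 47), Pmat (n, npar); returns dY (n, 47)."""
    n = Y.shape[0]
    dY = np.empty_like(Y)
    for i in range(n):
        cell_rhs_kernel(Y[i], Pmat[i], dY[i], False, True,
                        per_products[i], extra_dL[i])
    return dY
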