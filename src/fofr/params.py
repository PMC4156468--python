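"""Cell-level parameters: rate constants and membrane/secretion constants.

All kinetic constants are in nM and seconds (first-order: s^-1, second-order:
nM^-1 s^-1).  The receptor-trafficking constants follow the naming used in
the GPCR-desensitization literature for this system:

* ``k_61`` / ``k_62`` – GRK activation by PKA (catalytic rate of the
  PKAc:GRK complex) and GRK dephosphorylation;
* ``k_63`` / ``k_64`` – receptor phosphorylation by active GRK (catalytic
  rate of the GRKp:LR complex) and receptor dephosphorylation at the
  membrane;
* ``k_42`` – internalization of phosphorylated surface receptors;
* ``k_70`` – recycling of internalized receptors back to the surface; its
  inverse tau_D = 1/k_70 is the slowest time constant of the model and sets
  the interburst interval of the fast firing-rate oscillations;
* ``k_71`` – the recycling rate used by the slow-recovery phase-plane
  analysis (1e-8 s^-1 freezes the slow variable so the fast subsystem can
  be studied on its own).

``DE`` is the ratio of Gs-binding rates of phosphorylated vs unphosphorylated
receptors (< 1: desensitized receptors couple poorly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class CellParameters:
    # --- VIP binding ---
    kon_L: float = 0.01        # VIP association to R / Rp
    koff_L: float = 0.01       # VIP dissociation from uncoupled receptor (Kd 1 nM)
    koff_LG: float = 0.001     # VIP dissociation from Gs-precoupled receptor

    # --- Gs cycle ---
    kon_g_r: float = 1e-4      # Gs binding to unliganded R
    kon_g_lr: float = 1e-3     # Gs binding to VIP-bound receptor
    koff_g: float = 0.3
    DE: float = 0.0211           # phospho/unphospho ratio of Gs-binding rates
    kact: float = 0.0364        # GDP/GTP exchange in the agonist ternary complex
    kact0: float = 2e-5        # constitutive exchange in precoupled complexes
    khyd: float = 0.066        # GTP hydrolysis on free Galpha
    krea: float = 0.01         # GaGDP + Gbg reassociation

    # --- adenylate cyclase ---
    kon_ac: float = 1e-3
    koff_ac: float = 1.0
    khyd_ac: float = 0.066     # hydrolysis of AC-bound Galpha-GTP
    kon_atp: float = 1e-5
    koff_atp: float = 10.0
    kcat_ac: float = 10.0
    kon_atp_b: float = 1e-7    # basal (Gs-free) AC catalysis
    koff_atp_b: float = 10.0
    kcat_ac_b: float = 0.0366

    # --- phosphodiesterase ---
    kon_pde: float = 5e-3
    koff_pde: float = 5.0
    kcat_pde: float = 0.5
    kcat_pdep: float = 4.37     # PKA-phosphorylated PDE is ~9x more active
    kon_kpde: float = 1.22e-3
    koff_kpde: float = 0.1
    kcat_kpde: float = 0.5
    kdeph_pde: float = 0.002
    k_amp: float = 0.02        # AMP removal (nucleotide recycling)

    # --- PKA activation (sequential cAMP binding) ---
    kon_pka: float = 1e-3
    koff_pka1: float = 0.6
    koff_pka2: float = 0.4
    koff_pka3: float = 0.2
    koff_pka4: float = 0.1
    krel1: float = 1.0         # R2C2c4 -> R2Cc4 + C
    krb1: float = 1e-3
    krel2: float = 0.5         # R2Cc4 -> R2c4 + C
    krb2: float = 1e-3
    kreln: float = 0.2         # R2c4 -> R2 + 4 cAMP
    kasm: float = 1e-3         # R2 + C -> R2C
    kasm2: float = 1e-3        # R2C + C -> R2C2
    kdis0: float = 1e-5        # basal holoenzyme dissociation

    # --- PKA inhibitor / nuclear shuttling ---
    kon_pki: float = 0.01
    koff_pki: float = 0.01
    kin_n: float = 0.002
    kout_n: float = 0.01

    # --- GRK / receptor phosphorylation ---
    kon_grk: float = 1e-3
    koff_grk: float = 0.1
    k_61: float = 0.2
    k_62: float = 0.0166
    kon_grkr: float = 1e-3
    koff_grkr: float = 0.1
    k_63: float = 1.14
    k_64: float = 1e-4

    # --- internalization / recycling ---
    k_42: float = 5.0e-3
    k_deph_int: float = 0.01
    k_70: float = 5.31e-4      # tau_D = 1/k_70 ~ 31 min
    k_71: float = 1e-8         # slow-recovery analysis value

    # --- CREB ---
    kon_creb: float = 1e-3
    koff_creb: float = 0.1
    kcat_creb: float = 0.1
    k_crebd: float = 1e-3

    # --- CNG channels / firing / secretion ---
    g_CNG0: float = 1.0        # maximal CNG conductance (normalized units)
    K_CNG: float = 77.0       # cAMP half-activation (nM)
    n_CNG: float = 3.0         # CNG Hill coefficient
    per_independent_fraction: float = 0.0  # fraction of CNG driven by Per
    K_per: float = 12.0        # Per-product half-activation (clock units)
    n_per: float = 2.0
    I_threshold: float = 0.078   # firing threshold (conductance units)
    I_sat: float = 0.377         # current at which firing saturates
    F_max: float = 10.0        # saturated firing rate (Hz)

    # --- VIP pool ---
    VIP_0: float = 0.05        # steady-state VIP (nM) at zero firing
    k_L: float = 0.005         # VIP clearance (s^-1)
    k_sec: float = 0.0031      # VIP secretion gain (nM s^-1 per Hz)

    # --- flags (kept numeric so parameter vectors stay float arrays) ---
    atp_clamped: float = 1.0   # 1: ATP held constant; 0: AMP recycled to ATP

    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
            if v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        if not 0.0 <= self.per_independent_fraction <= 1.0:
            raise ValueError("per_independent_fraction must lie in [0, 1]")
        if self.DE <= 0:
            raise ValueError("DE must be > 0")
        if self.I_sat <= self.I_threshold:
            raise ValueError("I_sat must exceed I_threshold")

    def replace(self, **kwargs) -> "CellParameters":
        p = dataclasses.replace(self, **kwargs)
        p.validate()
        return p

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "CellParameters":
        return cls(**{n: float(v[i]) for i, n in enumerate(PARAM_NAMES)})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {n: float(getattr(self, n)) for n in PARAM_NAMES},
            sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CellParameters":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters in {path}: {sorted(unknown)}")
        p = cls(**data)
        p.validate()
        return p


PARAM_NAMES: list[str] = [f.name for f in dataclasses.fields(CellParameters)]
PIDX: dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

#: rate constants introduced on top of the receptor->cAMP core cascade; these
#: are the quantities the global sensitivity scan varies besides the initial
#: concentrations.
ADDED_PARAMETERS: list[str] = [
    "k_61", "k_62", "k_63", "k_64", "k_42", "k_70",
    "g_CNG0", "VIP_0", "I_threshold", "DE",
]
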