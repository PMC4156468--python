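"""Species registry for the single-cell VIP/VPAC2/cAMP signalling network.

The cell state is a 47-component vector of molecular concentrations (nM).
Index order is fixed and shared by the right-hand side, the trajectory
containers and all analysis code.  Conserved moieties (receptor, G-protein
subunits, AC, PDE, PKA subunits, GRK, PKI, CREB) are declared here with
per-species stoichiometric weights so that mass conservation can be checked
exactly on any trajectory.
"""

from __future__ import annotations

import numpy as np

#: (name, description) in state-vector order.
SPECIES: list[tuple[str, str]] = [
    ("L", "extracellular / perimembrane VIP"),
    ("R", "surface VPAC2 receptor, unphosphorylated, free"),
    ("LR", "VIP-bound surface receptor"),
    ("Rp", "surface receptor, GRK-phosphorylated"),
    ("LRp", "VIP-bound phosphorylated receptor"),
    ("RGs", "precoupled R:Gs(GDP) complex"),
    ("LRGs", "ternary VIP:R:Gs complex"),
    ("LRpGs", "ternary VIP:Rp:Gs complex"),
    ("RpGs", "precoupled Rp:Gs complex"),
    ("Rint", "internalized receptor, dephosphorylated"),
    ("Rintp", "internalized receptor, phosphorylated"),
    ("Gs", "GDP-bound heterotrimeric Gs (GDP.Gasbg)"),
    ("GaGTP", "free Galpha_s-GTP"),
    ("GaGDP", "free Galpha_s-GDP"),
    ("Gbg", "free Gbetagamma"),
    ("AC", "free adenylate cyclase"),
    ("GaAC", "Galpha_s(GTP):AC complex"),
    ("GaACATP", "Galpha_s:AC:ATP catalytic complex"),
    ("ACATP", "AC:ATP basal catalytic complex"),
    ("ATP", "ATP (clamped by default)"),
    ("cAMP", "cyclic AMP"),
    ("AMP", "AMP"),
    ("PDE", "cAMP phosphodiesterase, basal"),
    ("PDEcAMP", "PDE:cAMP complex"),
    ("PDEp", "PKA-phosphorylated PDE"),
    ("PDEpcAMP", "PDEp:cAMP complex"),
    ("PKACPDE", "PKAc:PDE phosphorylation complex"),
    ("R2C2", "PKA holoenzyme R2C2"),
    ("R2C2c1", "R2C2:(cAMP)"),
    ("R2C2c2", "R2C2:(cAMP)2"),
    ("R2C2c3", "R2C2:(cAMP)3"),
    ("R2C2c4", "R2C2:(cAMP)4"),
    ("R2Cc4", "R2C:(cAMP)4 release intermediate"),
    ("R2c4", "R2:(cAMP)4"),
    ("R2", "free PKA regulatory dimer"),
    ("R2C", "R2C reassembly intermediate"),
    ("PKAC", "free PKA catalytic subunit"),
    ("PKI", "cytoplasmic PKA inhibitor"),
    ("PKIPKAC", "PKI:PKAc complex"),
    ("PKAn", "nuclear PKA catalytic subunit"),
    ("GRK", "GRK, unphosphorylated"),
    ("PKACGRK", "PKAc:GRK complex"),
    ("GRKp", "PKA-phosphorylated (active) GRK"),
    ("GRKpLR", "GRKp:LR phosphorylation complex"),
    ("CREB", "inactive CREB"),
    ("PKAnCREB", "PKAn:CREB complex"),
    ("CREBa", "active (phospho) CREB"),
]

N_SPECIES = len(SPECIES)
assert N_SPECIES == 47

SPECIES_NAMES: list[str] = [name for name, _ in SPECIES]
IDX: dict[str, int] = {name: i for i, (name, _) in enumerate(SPECIES)}


def _moiety(weights: dict[str, float]) -> np.ndarray:
    w = np.zeros(N_SPECIES)
    for name, x in weights.items():
        w[IDX[name]] = x
    return w


#: moiety name -> stoichiometric weight vector; y @ w is constant on any
#: trajectory (receptor conservation includes the internalized pool because
#: recycling k_70 returns receptors rather than synthesising new ones).
CONSERVED_MOIETIES: dict[str, np.ndarray] = {
    "receptor": _moiety({s: 1.0 for s in (
        "R", "LR", "Rp", "LRp", "RGs", "LRGs", "LRpGs", "RpGs",
        "Rint", "Rintp", "GRKpLR")}),
    "G_alpha": _moiety({s: 1.0 for s in (
        "Gs", "RGs", "LRGs", "LRpGs", "RpGs", "GaGTP", "GaGDP",
        "GaAC", "GaACATP")}),
    "G_betagamma": _moiety({s: 1.0 for s in (
        "Gs", "RGs", "LRGs", "LRpGs", "RpGs", "Gbg")}),
    "AC": _moiety({s: 1.0 for s in ("AC", "GaAC", "GaACATP", "ACATP")}),
    "PDE": _moiety({s: 1.0 for s in (
        "PDE", "PDEcAMP", "PDEp", "PDEpcAMP", "PKACPDE")}),
    "PKA_catalytic": _moiety({
        "R2C2": 2.0, "R2C2c1": 2.0, "R2C2c2": 2.0, "R2C2c3": 2.0,
        "R2C2c4": 2.0, "R2Cc4": 1.0, "R2C": 1.0, "PKAC": 1.0,
        "PKIPKAC": 1.0, "PKAn": 1.0, "PKACGRK": 1.0, "PKACPDE": 1.0,
        "PKAnCREB": 1.0}),
    "PKA_regulatory": _moiety({s: 1.0 for s in (
        "R2C2", "R2C2c1", "R2C2c2", "R2C2c3", "R2C2c4",
        "R2Cc4", "R2c4", "R2", "R2C")}),
    "GRK": _moiety({s: 1.0 for s in ("GRK", "PKACGRK", "GRKp", "GRKpLR")}),
    "PKI": _moiety({s: 1.0 for s in ("PKI", "PKIPKAC")}),
    "CREB": _moiety({s: 1.0 for s in ("CREB", "PKAnCREB", "CREBa")}),
}

#: surface receptor species (numerator of the Fig.-2 "membrane / total" ratio)
SURFACE_RECEPTOR = _moiety({s: 1.0 for s in (
    "R", "LR", "Rp", "LRp", "RGs", "LRGs", "LRpGs", "RpGs", "GRKpLR")})

#: all receptor species (denominator of the same ratio)
TOTAL_RECEPTOR = CONSERVED_MOIETIES["receptor"]


def conserved_totals(y: np.ndarray) -> dict[str, np.ndarray]:
    """Weighted totals of every conserved moiety for state(s) ``y``.

    ``y`` has shape (..., 47); each total has shape (...).
    """
    y = np.asarray(y)
    return {name: y @ w for name, w in CONSERVED_MOIETIES.items()}


class SpeciesState:
    """A named view over a 47-component concentration vector (nM)."""

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != N_SPECIES:
            raise ValueError(
                f"expected {N_SPECIES} species, got {values.shape[-1]}")
        self.values = values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[..., IDX[name]]

    def __setitem__(self, name: str, value) -> None:
        self.values[..., IDX[name]] = value

    def copy(self) -> "SpeciesState":
        return SpeciesState(self.values.copy())

    def surface_fraction(self) -> np.ndarray:
        tot = self.values @ TOTAL_RECEPTOR
        return (self.values @ SURFACE_RECEPTOR) / np.where(tot > 0, tot, 1.0)

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.values[..., i])
                for i, (name, _) in enumerate(SPECIES)}

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesState({self.values!r})"
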