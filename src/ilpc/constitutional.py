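"""Constitutional (0D/1D) molecular descriptors, 41 per ion, 82 per IL.

Everything here is a pure function of the frozen :class:`MolecularGraph`:
no geometry, no conformers.  The block covers

* weighted sums and means — MW, AMW and the carbon-scaled cumulative
  Sanderson electronegativity (Se), polarizability (Sp), first ionization
  potential (Si) and van der Waals volume (Sv), with means Me/Mp/Mi;
* graph counts — atoms, skeleton atoms, bonds, multiple/double/triple/
  aromatic bonds, conventional bond-order sum, aromatic ratio, rotatable
  bonds and their fraction;
* element counts and percentages;
* carbon hybridization counts (sp3/sp2/sp).

Implicit hydrogens are always materialized into nH, nAT, nBT, MW and the
weighted sums.  Aromatic bonds contribute 1.5 to SCBO (conventional
bond-order convention).  A rotatable bond is a non-ring, non-aromatic single
bond whose two heavy endpoints each carry at least two heavy neighbours —
a purely topological rule, applied uniformly (no amide exclusion).

The registry (name order) is versioned: downstream models record which
registry they were fitted with.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_io import MolecularGraph
from .elements import DEFAULT_ELEMENT_TABLE, ElementTable

REGISTRY_VERSION = "ilpc-registry-41-v1"

#: fixed slot order of the per-ion constitutional block
REGISTRY: tuple[str, ...] = (
    # weighted sums / means
    "MW", "AMW", "Se", "Sp", "Si", "Sv", "Me", "Mp", "Mi",
    # graph counts
    "nAT", "nSK", "nBT", "nBO", "nBM", "SCBO", "ARR", "RBN", "RBF",
    "nDB", "nTB", "nAB",
    # element counts
    "nH", "nC", "nN", "nO", "nP", "nS", "nF", "nCl", "nBr", "nI",
    "nX", "nHet",
    # percentages
    "H%", "C%", "N%", "O%", "X%",
    # carbon hybridization
    "nCsp3", "nCsp2", "nCsp",
)

assert len(REGISTRY) == 41

_HALOGENS = ("F", "Cl", "Br", "I")


@dataclass(frozen=True)
class ConstitutionalVector:
    """The 41 named descriptor values for one ion, in registry order."""

    values: dict[str, float]

    def __post_init__(self):
        if tuple(self.values) != REGISTRY:
            raise ValueError("descriptor names/order do not match the registry "
                             f"({REGISTRY_VERSION})")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass(frozen=True)
class ILDescriptorVector:
    """82 named values for one IL: cation block (^C) then anion block (^A)."""

    il_id: str
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def element_counts(g: MolecularGraph) -> dict[str, float]:
    """Atom-composition counts; nH includes implicit hydrogens."""
    n_h = sum(h for _, _, h in g.atoms)
    counts = {sym: 0 for sym in ("C", "N", "O", "P", "S", *_HALOGENS)}
    for sym, _, _ in g.atoms:
        if sym == "H":
            n_h += 1  # rare explicit-H atom entries count as hydrogens
        elif sym in counts:
            counts[sym] += 1
        else:
            # still a heavy atom; nHet/nSK pick it up, element table may reject later
            counts.setdefault(sym, 0)
            counts[sym] += 1
    n_sk = sum(1 for sym, _, _ in g.atoms if sym != "H")
    n_at = n_sk + n_h
    n_x = sum(counts[h] for h in _HALOGENS)
    n_het = n_sk - counts["C"]
    return {
        "nH": float(n_h), "nC": float(counts["C"]), "nN": float(counts["N"]),
        "nO": float(counts["O"]), "nP": float(counts["P"]), "nS": float(counts["S"]),
        "nF": float(counts["F"]), "nCl": float(counts["Cl"]),
        "nBr": float(counts["Br"]), "nI": float(counts["I"]),
        "nX": float(n_x), "nHet": float(n_het),
        "nAT": float(n_at), "nSK": float(n_sk),
        "H%": 100.0 * n_h / n_at, "C%": 100.0 * counts["C"] / n_at,
        "N%": 100.0 * counts["N"] / n_at, "O%": 100.0 * counts["O"] / n_at,
        "X%": 100.0 * n_x / n_at,
    }


def _is_rotatable(g: MolecularGraph, bond: tuple) -> bool:
    i, j, order, in_ring = bond
    if order != 1 or in_ring:
        return False
    return g.heavy_degree(i) >= 2 and g.heavy_degree(j) >= 2


def bond_block(g: MolecularGraph) -> dict[str, float]:
    """Bond counts over the full and H-depleted graphs.

    nBT counts every bond including X–H; nBO only heavy–heavy bonds; SCBO is
    the conventional bond-order sum of the H-depleted graph (aromatic = 1.5).
    """
    n_h = sum(h for _, _, h in g.atoms)
    n_bo = len(g.bonds)
    n_bt = n_bo + n_h
    n_db = sum(1 for b in g.bonds if b[2] == 2)
    n_tb = sum(1 for b in g.bonds if b[2] == 3)
    n_ab = sum(1 for b in g.bonds if b[2] == "aromatic")
    scbo = sum(1.5 if b[2] == "aromatic" else float(b[2]) for b in g.bonds)
    rbn = sum(1 for b in g.bonds if _is_rotatable(g, b))
    return {
        "nBT": float(n_bt), "nBO": float(n_bo), "nBM": float(n_db + n_tb + n_ab),
        "SCBO": scbo, "ARR": (n_ab / n_bo) if n_bo else 0.0,
        "RBN": float(rbn), "RBF": (rbn / n_bt) if n_bt else 0.0,
        "nDB": float(n_db), "nTB": float(n_tb), "nAB": float(n_ab),
    }


def weighted_sums(g: MolecularGraph,
                  table: ElementTable = DEFAULT_ELEMENT_TABLE) -> dict[str, float]:
    """MW plus carbon-scaled cumulative sums Se/Sp/Si/Sv and means.

    Sums run over *all* atoms, implicit hydrogens included.  Formal charge
    never changes the lookup.
    """
    mw = 0.0
    sums = {"Se": 0.0, "Sp": 0.0, "Si": 0.0, "Sv": 0.0}
    scale_of = {"Se": "electronegativity", "Sp": "polarizability",
                "Si": "ionization", "Sv": "vdw_volume"}
    n_at = 0
    for sym, _, n_h in g.atoms:
        for atom_sym, mult in ((sym, 1), ("H", n_h)):
            if mult == 0:
                continue
            mw += mult * table.mass(atom_sym)
            for key, scale in scale_of.items():
                sums[key] += mult * table.carbon_scaled(atom_sym, scale)
            n_at += mult
    return {
        "MW": mw, "AMW": mw / n_at,
        **sums,
        "Me": sums["Se"] / n_at, "Mp": sums["Sp"] / n_at, "Mi": sums["Si"] / n_at,
    }


def hybridization_counts(g: MolecularGraph) -> dict[str, float]:
    """Carbon sp3/sp2/sp counts from bond orders.

    Only single bonds -> sp3; one double bond or any aromatic bond -> sp2;
    a triple bond or two double bonds -> sp.
    """
    sp3 = sp2 = sp = 0
    for idx, (sym, _, _) in enumerate(g.atoms):
        if sym != "C":
            continue
        orders = [b[2] for b in g.bonds if idx in (b[0], b[1])]
        n_double = orders.count(2)
        if 3 in orders or n_double >= 2:
            sp += 1
        elif n_double == 1 or "aromatic" in orders:
            sp2 += 1
        else:
            sp3 += 1
    return {"nCsp3": float(sp3), "nCsp2": float(sp2), "nCsp": float(sp)}


def constitutional_vector(g: MolecularGraph,
                          table: ElementTable = DEFAULT_ELEMENT_TABLE
                          ) -> ConstitutionalVector:
    """All 41 slots in fixed registry order for one ion."""
    parts: dict[str, float] = {}
    parts.update(weighted_sums(g, table))
    parts.update(element_counts(g))
    parts.update(bond_block(g))
    parts.update(hybridization_counts(g))
    return ConstitutionalVector(values={name: parts[name] for name in REGISTRY})


def il_vector(cation: ConstitutionalVector, anion: ConstitutionalVector,
              il_id: str) -> ILDescriptorVector:
    """Concatenate cation and anion blocks into the 82-slot IL vector."""
    values = {f"{name}^C": cation[name] for name in REGISTRY}
    values.update({f"{name}^A": anion[name] for name in REGISTRY})
    return ILDescriptorVector(il_id=il_id, values=values)


IL_REGISTRY: tuple[str, ...] = tuple(
    [f"{n}^C" for n in REGISTRY] + [f"{n}^A" for n in REGISTRY])
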