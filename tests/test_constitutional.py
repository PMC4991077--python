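"""Descriptor engine checked against a naive oracle on hand-specified ions.

Each library entry gives the ion's SMILES *and* an independently hand-written
atom/bond list (element, formal charge, implicit H; i, j, order, in-ring).
The oracle computes every descriptor by direct naive enumeration of those
lists; the package route goes SMILES -> RDKit graph -> registry vector.
Only multiset content matters, so the hand atom ordering is free.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ilpc.chem_io import parse_structure
from ilpc.constitutional import (REGISTRY, ConstitutionalVector,
                                 constitutional_vector, il_vector)
from ilpc.elements import DEFAULT_ELEMENT_TABLE as ET, UnsupportedElementError
from ilpc.fixtures import FAMILIES, cation_smiles

AR = "aromatic"

# -- hand-specified ion library (atoms: (symbol, charge, implicit H)) --------
IONS = {
    "chloride": ("[Cl-]", [("Cl", -1, 0)], []),
    "bromide": ("[Br-]", [("Br", -1, 0)], []),
    "iodide": ("[I-]", [("I", -1, 0)], []),
    "hydroxide": ("[OH-]", [("O", -1, 1)], []),
    "tetrafluoroborate": (
        "[B-](F)(F)(F)F",
        [("B", -1, 0), ("F", 0, 0), ("F", 0, 0), ("F", 0, 0), ("F", 0, 0)],
        [(0, 1, 1, False), (0, 2, 1, False), (0, 3, 1, False), (0, 4, 1, False)]),
    "hexafluorophosphate": (
        "F[P-](F)(F)(F)(F)F",
        [("P", -1, 0)] + [("F", 0, 0)] * 6,
        [(0, k, 1, False) for k in range(1, 7)]),
    "acetate": (
        "CC(=O)[O-]",
        [("C", 0, 3), ("C", 0, 0), ("O", 0, 0), ("O", -1, 0)],
        [(0, 1, 1, False), (1, 2, 2, False), (1, 3, 1, False)]),
    "nitrate": (
        "[O-][N+](=O)[O-]",
        [("O", -1, 0), ("N", 1, 0), ("O", 0, 0), ("O", -1, 0)],
        [(0, 1, 1, False), (1, 2, 2, False), (1, 3, 1, False)]),
    "glycinate": (
        "NCC(=O)[O-]",
        [("N", 0, 2), ("C", 0, 2), ("C", 0, 0), ("O", 0, 0), ("O", -1, 0)],
        [(0, 1, 1, False), (1, 2, 1, False), (2, 3, 2, False), (2, 4, 1, False)]),
    "alaninate": (
        "CC(N)C(=O)[O-]",
        [("C", 0, 3), ("C", 0, 1), ("N", 0, 2), ("C", 0, 0), ("O", 0, 0),
         ("O", -1, 0)],
        [(0, 1, 1, False), (1, 2, 1, False), (1, 3, 1, False),
         (3, 4, 2, False), (3, 5, 1, False)]),
    "mesylate": (
        "CS(=O)(=O)[O-]",
        [("C", 0, 3), ("S", 0, 0), ("O", 0, 0), ("O", 0, 0), ("O", -1, 0)],
        [(0, 1, 1, False), (1, 2, 2, False), (1, 3, 2, False), (1, 4, 1, False)]),
    "triflate": (
        "C(F)(F)(F)S(=O)(=O)[O-]",
        [("C", 0, 0), ("F", 0, 0), ("F", 0, 0), ("F", 0, 0), ("S", 0, 0),
         ("O", 0, 0), ("O", 0, 0), ("O", -1, 0)],
        [(0, 1, 1, False), (0, 2, 1, False), (0, 3, 1, False), (0, 4, 1, False),
         (4, 5, 2, False), (4, 6, 2, False), (4, 7, 1, False)]),
    "tfsi": (
        "C(F)(F)(F)S(=O)(=O)[N-]S(=O)(=O)C(F)(F)F",
        [("C", 0, 0), ("F", 0, 0), ("F", 0, 0), ("F", 0, 0), ("S", 0, 0),
         ("O", 0, 0), ("O", 0, 0), ("N", -1, 0), ("S", 0, 0), ("O", 0, 0),
         ("O", 0, 0), ("C", 0, 0), ("F", 0, 0), ("F", 0, 0), ("F", 0, 0)],
        [(0, 1, 1, False), (0, 2, 1, False), (0, 3, 1, False), (0, 4, 1, False),
         (4, 5, 2, False), (4, 6, 2, False), (4, 7, 1, False), (7, 8, 1, False),
         (8, 9, 2, False), (8, 10, 2, False), (8, 11, 1, False),
         (11, 12, 1, False), (11, 13, 1, False), (11, 14, 1, False)]),
    "cyanoacetate": (  # nitrile carbon exercises the sp count
        "N#CCC(=O)[O-]",
        [("N", 0, 0), ("C", 0, 0), ("C", 0, 2), ("C", 0, 0), ("O", 0, 0),
         ("O", -1, 0)],
        [(0, 1, 3, False), (1, 2, 1, False), (2, 3, 1, False),
         (3, 4, 2, False), (3, 5, 1, False)]),
    "tetramethylammonium": (
        "C[N+](C)(C)C",
        [("N", 1, 0)] + [("C", 0, 3)] * 4,
        [(0, k, 1, False) for k in range(1, 5)]),
    "tetramethylphosphonium": (
        "C[P+](C)(C)C",
        [("P", 1, 0)] + [("C", 0, 3)] * 4,
        [(0, k, 1, False) for k in range(1, 5)]),
    "trimethylsulfonium": (
        "C[S+](C)C",
        [("S", 1, 0)] + [("C", 0, 3)] * 3,
        [(0, k, 1, False) for k in range(1, 4)]),
    "ethylammonium": (
        "CC[NH3+]",
        [("C", 0, 3), ("C", 0, 2), ("N", 1, 3)],
        [(0, 1, 1, False), (1, 2, 1, False)]),
    "tetraethylammonium": (
        "CC[N+](CC)(CC)CC",
        [("N", 1, 0), ("C", 0, 2), ("C", 0, 3), ("C", 0, 2), ("C", 0, 3),
         ("C", 0, 2), ("C", 0, 3), ("C", 0, 2), ("C", 0, 3)],
        [(0, 1, 1, False), (1, 2, 1, False), (0, 3, 1, False), (3, 4, 1, False),
         (0, 5, 1, False), (5, 6, 1, False), (0, 7, 1, False), (7, 8, 1, False)]),
    "dimethylimidazolium": (
        "Cn1cc[n+](C)c1",
        [("C", 0, 3), ("N", 0, 0), ("C", 0, 1), ("C", 0, 1), ("N", 1, 0),
         ("C", 0, 3), ("C", 0, 1)],
        [(0, 1, 1, False), (1, 2, AR, True), (2, 3, AR, True), (3, 4, AR, True),
         (4, 5, 1, False), (4, 6, AR, True), (6, 1, AR, True)]),
    "methylpyridinium": (
        "C[n+]1ccccc1",
        [("C", 0, 3), ("N", 1, 0), ("C", 0, 1), ("C", 0, 1), ("C", 0, 1),
         ("C", 0, 1), ("C", 0, 1)],
        [(0, 1, 1, False), (1, 2, AR, True), (2, 3, AR, True), (3, 4, AR, True),
         (4, 5, AR, True), (5, 6, AR, True), (6, 1, AR, True)]),
    "dimethylpyrrolidinium": (
        "C[N+]1(C)CCCC1",
        [("N", 1, 0), ("C", 0, 3), ("C", 0, 3), ("C", 0, 2), ("C", 0, 2),
         ("C", 0, 2), ("C", 0, 2)],
        [(0, 1, 1, False), (0, 2, 1, False), (0, 3, 1, True), (3, 4, 1, True),
         (4, 5, 1, True), (5, 6, 1, True), (6, 0, 1, True)]),
    "ethylmethylimidazolium": (
        "CCn1cc[n+](C)c1",
        [("C", 0, 3), ("C", 0, 2), ("N", 0, 0), ("C", 0, 1), ("C", 0, 1),
         ("N", 1, 0), ("C", 0, 3), ("C", 0, 1)],
        [(0, 1, 1, False), (1, 2, 1, False), (2, 3, AR, True), (3, 4, AR, True),
         (4, 5, AR, True), (5, 6, 1, False), (5, 7, AR, True), (7, 2, AR, True)]),
}


def naive_vector(atoms, bonds):
    """Independent brute-force descriptor computation from explicit lists."""
    n_h = sum(h for _, _, h in atoms)
    n_sk = len(atoms)
    n_at = n_sk + n_h
    count = lambda sym: sum(1 for s, _, _ in atoms if s == sym)
    n_x = count("F") + count("Cl") + count("Br") + count("I")

    def wsum(scale):
        tot = 0.0
        for s, _, h in atoms:
            tot += ET.value(s, scale) / ET.value("C", scale)
            tot += h * ET.value("H", scale) / ET.value("C", scale)
        return tot

    mw = sum(ET.mass(s) + h * ET.mass("H") for s, _, h in atoms)
    n_bo = len(bonds)
    n_bt = n_bo + n_h
    n_db = sum(1 for b in bonds if b[2] == 2)
    n_tb = sum(1 for b in bonds if b[2] == 3)
    n_ab = sum(1 for b in bonds if b[2] == AR)
    scbo = sum(1.5 if b[2] == AR else b[2] for b in bonds)
    deg = [0] * n_sk
    for i, j, _, _ in bonds:
        deg[i] += 1
        deg[j] += 1
    rbn = sum(1 for i, j, o, ring in bonds
              if o == 1 and not ring and deg[i] >= 2 and deg[j] >= 2)
    sp3 = sp2 = sp = 0
    for idx, (s, _, _) in enumerate(atoms):
        if s != "C":
            continue
        orders = [b[2] for b in bonds if idx in (b[0], b[1])]
        if 3 in orders or orders.count(2) >= 2:
            sp += 1
        elif 2 in orders or AR in orders:
            sp2 += 1
        else:
            sp3 += 1
    return {
        "MW": mw, "AMW": mw / n_at,
        "Se": wsum("electronegativity"), "Sp": wsum("polarizability"),
        "Si": wsum("ionization"), "Sv": wsum("vdw_volume"),
        "Me": wsum("electronegativity") / n_at, "Mp": wsum("polarizability") / n_at,
        "Mi": wsum("ionization") / n_at,
        "nAT": n_at, "nSK": n_sk, "nBT": n_bt, "nBO": n_bo,
        "nBM": n_db + n_tb + n_ab, "SCBO": scbo,
        "ARR": n_ab / n_bo if n_bo else 0.0, "RBN": rbn,
        "RBF": rbn / n_bt if n_bt else 0.0,
        "nDB": n_db, "nTB": n_tb, "nAB": n_ab,
        "nH": n_h, "nC": count("C"), "nN": count("N"), "nO": count("O"),
        "nP": count("P"), "nS": count("S"), "nF": count("F"),
        "nCl": count("Cl"), "nBr": count("Br"), "nI": count("I"),
        "nX": n_x, "nHet": n_sk - count("C"),
        "H%": 100 * n_h / n_at, "C%": 100 * count("C") / n_at,
        "N%": 100 * count("N") / n_at, "O%": 100 * count("O") / n_at,
        "X%": 100 * n_x / n_at,
        "nCsp3": sp3, "nCsp2": sp2, "nCsp": sp,
    }


@pytest.mark.parametrize("name", sorted(IONS))
def test_full_vector_matches_naive_oracle(name):
    smiles, atoms, bonds = IONS[name]
    got = constitutional_vector(parse_structure(smiles))
    want = naive_vector(atoms, bonds)
    for slot in REGISTRY:
        assert got[slot] == pytest.approx(want[slot], abs=1e-12), slot


def test_registry_is_41_slots():
    assert len(REGISTRY) == 41
    v = constitutional_vector(parse_structure("C[N+](C)(C)C"))
    assert len(v.values) == 41
    assert all(math.isfinite(x) for x in v.values.values())


def test_registry_order_enforced():
    v = constitutional_vector(parse_structure("[Cl-]"))
    shuffled = dict(reversed(list(v.values.items())))
    with pytest.raises(ValueError, match="registry"):
        ConstitutionalVector(values=shuffled)


def test_chloride_carbon_slots_zero():
    v = constitutional_vector(parse_structure("[Cl-]"))
    for slot in ("nC", "nCsp3", "nCsp2", "nCsp", "C%", "nBT", "SCBO", "RBF", "ARR"):
        assert v[slot] == 0


@pytest.mark.parametrize("smiles_a,smiles_b", [
    ("C[N+](C)(C)C", "[N+](C)(C)(C)C"),
    ("CCn1cc[n+](C)c1", "Cn1cc[n+](CC)c1"),
    ("CC(=O)[O-]", "[O-]C(C)=O"),
])
def test_atom_order_invariance(smiles_a, smiles_b):
    va = constitutional_vector(parse_structure(smiles_a))
    vb = constitutional_vector(parse_structure(smiles_b))
    assert va.values == pytest.approx(vb.values)


def test_rotatable_bond_degree_rule():
    # butyl chain on trimethylammonium: N-C and the two interior C-C bonds
    # have both endpoints with heavy-degree >= 2; the terminal C-C does not
    v = constitutional_vector(parse_structure("CCCC[N+](C)(C)C"))
    assert v["RBN"] == 3


def test_unsupported_element_named():
    with pytest.raises(UnsupportedElementError, match="Se"):
        constitutional_vector(parse_structure("[SeH-]"))


def test_il_vector_concatenation():
    cat = constitutional_vector(parse_structure("C[N+](C)(C)C"))
    an = constitutional_vector(parse_structure("[Cl-]"))
    ilv = il_vector(cat, an, "il1")
    assert len(ilv.values) == 82
    assert list(ilv.values)[:41] == [f"{n}^C" for n in REGISTRY]
    assert {n: ilv[f"{n}^C"] for n in REGISTRY} == cat.values
    swapped = il_vector(an, cat, "il1")
    assert swapped.values != ilv.values


@given(family=st.sampled_from(FAMILIES), chain=st.integers(1, 12))
@settings(max_examples=60, deadline=None)
def test_count_identities_on_generated_cations(family, chain):
    v = constitutional_vector(parse_structure(cation_smiles(family, chain)))
    assert v["nAT"] == v["nSK"] + v["nH"]
    assert v["nBT"] == v["nBO"] + v["nH"]
    assert v["nBM"] == v["nDB"] + v["nTB"] + v["nAB"]
    assert v["SCBO"] >= v["nBO"]
    assert v["nCsp3"] + v["nCsp2"] + v["nCsp"] <= v["nC"]
    assert v["H%"] == pytest.approx(100 * v["nH"] / v["nAT"])
    assert v["X%"] == pytest.approx(100 * v["nX"] / v["nAT"])
    assert v["Me"] * v["nAT"] == pytest.approx(v["Se"])
    assert v["AMW"] == pytest.approx(v["MW"] / v["nAT"])
    assert 0 <= v["RBF"] <= 1 and 0 <= v["ARR"] <= 1


@given(family=st.sampled_from(FAMILIES), chain=st.integers(1, 11))
@settings(max_examples=40, deadline=None)
def test_homologous_series_monotonicity(family, chain):
    v1 = constitutional_vector(parse_structure(cation_smiles(family, chain)))
    v2 = constitutional_vector(parse_structure(cation_smiles(family, chain + 1)))
    for slot in ("MW", "nAT", "nC", "nH", "nCsp3"):
        assert v2[slot] > v1[slot], slot
    assert v2["RBN"] >= v1["RBN"]
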