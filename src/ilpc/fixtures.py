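"""Deterministic synthetic reference sets.

The published 172-IL reference collection lives in a supplementary file
that is not redistributable, so every stage of this package is exercised
against a synthetic stand-in built here.  The generator emulates the
*composition* of that collection, not its census: six cation families
(imidazolium, ammonium, phosphonium, pyridinium, pyrrolidinium, sulfonium)
with varying alkyl chain lengths, paired with four anion classes (halide,
tetrafluoroborate-like, TFSI-like, amino-acid-like) instead of the original
38 anions.  The pairing mirrors real IL chemistry rather than a full
factorial: the small-cation families carry halide, fluoroborate-like and
TFSI-like anions, while amino-acid anions appear with the large
tetraalkylammonium and -phosphonium cations (phosphonium cores are the
largest, and carry the larger amino acids).  That composition is what gives
the reference map its six-cluster anatomy — small cations with halides (A),
with fluoroborates (B), with TFSI (C); large ammonium with amino
acids/fluoroborates (D), large phosphonium with large amino acids (E),
large cations with halides (F).  Property values follow the trend structure
the map encodes —

* viscosity grows with cation size and drops for TFSI-like anions,
* K_OW grows with total ion size,
* water solubility falls with cation size but rises along the anion-size
  axis (halide ILs lowest through the TFSI-like ILs highest),
* enthalpy of fusion grows with anion size —

with Gaussian noise on the standardized latent scale.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .chem_io import ILRecord, parse_structure
from .constitutional import constitutional_vector
from .property_map import PropertyRecord

FAMILIES = ("imidazolium", "ammonium", "phosphonium",
            "pyridinium", "pyrrolidinium", "sulfonium")
ANION_CLASSES = ("halide", "BF4-like", "TFSI-like", "amino-acid-like")

#: families whose cations stay small vs. grow large (tetraalkyl cores)
SMALL_CATION_FAMILIES = ("imidazolium", "pyridinium", "pyrrolidinium", "sulfonium")
LARGE_CATION_FAMILIES = ("ammonium", "phosphonium")

_CATION_TEMPLATES = {
    # alkyl chain of k carbons is prepended as "C"*k
    "imidazolium": "n1cc[n+](C)c1",              # 1-alkyl-3-methylimidazolium
    "ammonium": "[N+](CCCC)(CCCC)CCCC",          # alkyl-tributylammonium
    "phosphonium": "[P+](CCCCCC)(CCCCCC)CCCCCC", # alkyl-trihexylphosphonium
    "pyridinium": "[n+]1ccccc1",                 # N-alkylpyridinium
    "pyrrolidinium": "[N+]1(C)CCCC1",            # N-alkyl-N-methylpyrrolidinium
    "sulfonium": "[S+](C)C",                     # alkyl-dimethylsulfonium
}

_ANION_SMILES = {
    "halide": ("[Cl-]", "[Br-]"),
    "BF4-like": ("[B-](F)(F)(F)F", "F[P-](F)(F)(F)(F)F"),
    "TFSI-like": ("C(F)(F)(F)S(=O)(=O)[N-]S(=O)(=O)C(F)(F)F",
                  "C(F)(F)(F)S(=O)(=O)[N-]S(=O)(=O)F"),
    # ordered small -> large; ammonium draws the small ones, phosphonium the large
    "amino-acid-like": ("NCC(=O)[O-]", "CC(N)C(=O)[O-]",
                        "CC(C)C(N)C(=O)[O-]", "CC(C)CC(N)C(=O)[O-]"),
}

#: anion-class rotation per cation family (mirrors the reference census)
_FAMILY_ANION_CYCLE = {
    "imidazolium": ("halide", "BF4-like", "TFSI-like"),
    "pyridinium": ("halide", "BF4-like", "TFSI-like"),
    "pyrrolidinium": ("halide", "BF4-like", "TFSI-like"),
    "sulfonium": ("halide", "BF4-like", "TFSI-like"),
    "ammonium": ("amino-acid-like", "BF4-like", "halide"),
    "phosphonium": ("amino-acid-like", "amino-acid-like", "halide"),
}

#: additive viscosity offset per anion class on the log-latent scale
_ANION_VISC_OFFSET = {"halide": 0.6, "BF4-like": 0.0,
                      "TFSI-like": -1.0, "amino-acid-like": 0.4}

def _truth_cluster(family: str, anion_class: str) -> str:
    """Generator's intended cluster letter, mirroring the reference-map anatomy."""
    if family in SMALL_CATION_FAMILIES:
        return {"halide": "A", "BF4-like": "B", "TFSI-like": "C",
                "amino-acid-like": "B"}[anion_class]
    if anion_class == "halide":
        return "F"
    return "E" if family == "phosphonium" else "D"


@dataclass(frozen=True)
class FixtureSpec:
    n_per_family: int = 10
    families: tuple[str, ...] = FAMILIES
    anion_classes: tuple[str, ...] = ANION_CLASSES
    chain_range: tuple[int, int] = (2, 8)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.families:
            raise ValueError("at least one cation family is required")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown cation families: {sorted(unknown)}")
        unknown = set(self.anion_classes) - set(ANION_CLASSES)
        if unknown:
            raise ValueError(f"unknown anion classes: {sorted(unknown)}")


def cation_smiles(family: str, chain_length: int) -> str:
    if chain_length < 1:
        raise ValueError("chain length must be >= 1")
    return "C" * chain_length + _CATION_TEMPLATES[family]


def generate_reference_set(spec: FixtureSpec
                           ) -> tuple[list[ILRecord], list[PropertyRecord], dict]:
    """Build the synthetic reference set: ILs, property values, truth record.

    Returns (il_records, property_records, truth); ``truth`` carries the
    generator's own labels (family, anion class, truth cluster letter) and
    latent parameters, for comparison with pipeline output.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ILRecord] = []
    meta: list[dict] = []
    lo, hi = spec.chain_range
    counter = 0
    for family in spec.families:
        cycle = tuple(a for a in _FAMILY_ANION_CYCLE[family]
                      if a in spec.anion_classes) or spec.anion_classes
        for i in range(spec.n_per_family):
            counter += 1
            anion_class = cycle[i % len(cycle)]
            chain = int(rng.integers(lo, hi + 1))
            a_choices = _ANION_SMILES[anion_class]
            if anion_class == "amino-acid-like":
                # ammonium pairs with the small amino acids, phosphonium the large
                a_choices = a_choices[2:] if family == "phosphonium" else a_choices[:2]
            anion = a_choices[int(rng.integers(len(a_choices)))]
            il_id = f"IL{counter:03d}"
            cat_smiles = cation_smiles(family, chain)
            records.append(ILRecord(il_id=il_id,
                                    cation=parse_structure(cat_smiles),
                                    anion=parse_structure(anion),
                                    family=family))
            size_group = "small" if family in SMALL_CATION_FAMILIES else "large"
            meta.append({"il_id": il_id, "family": family,
                         "anion_class": anion_class, "chain_length": chain,
                         "cation_smiles": cat_smiles, "anion_smiles": anion,
                         "cation_size_group": size_group,
                         "truth_cluster": _truth_cluster(family, anion_class)})

    # latent size coordinates: z-scored cation / anion molecular weights
    cat_mw = np.array([constitutional_vector(r.cation)["MW"] for r in records])
    an_mw = np.array([constitutional_vector(r.anion)["MW"] for r in records])
    z_cat = (cat_mw - cat_mw.mean()) / cat_mw.std()
    z_an = (an_mw - an_mw.mean()) / an_mw.std()
    z_tot = (z_cat + z_an) / np.sqrt(2.0)

    properties: list[PropertyRecord] = []
    latents = {
        # property -> (center, scale, latent values, units, log-scale?)
        "viscosity": (4.0, 1.2, z_cat + np.array(
            [_ANION_VISC_OFFSET[m["anion_class"]] for m in meta]), "cP", True),
        "Kow": (0.0, 1.0, z_tot, "-", True),
        "solubility": (4.0, 1.2, (-z_cat + 0.6 * z_an) / np.sqrt(1.36), "g/L", True),
        "enthalpy_of_fusion": (25.0, 8.0, z_an, "kJ/mol", False),
    }
    for prop, (center, scale, latent, units, is_log) in latents.items():
        noisy = latent + rng.normal(0.0, spec.noise_sd, size=len(records))
        raw = center + scale * noisy
        values = np.exp(raw) if is_log else raw
        for rec, v in zip(records, values):
            properties.append(PropertyRecord(il_id=rec.il_id, property=prop,
                                             value=float(v), units=units))

    truth = {
        "spec": asdict(spec),
        "ils": meta,
        "latent": {"z_cation_mw": z_cat.tolist(), "z_anion_mw": z_an.tolist(),
                   "z_total": z_tot.tolist()},
        "trend_structure": {
            "viscosity": "+cation size, anion-class offsets (TFSI lowest)",
            "Kow": "+total ion size",
            "solubility": "-cation size +0.6 anion size",
            "enthalpy_of_fusion": "+anion size",
        },
    }
    return records, properties, truth


def generate_descriptor_table(n: int, p: int, latent_rank: int, seed: int,
                              variance_fractions: tuple[float, ...] | None = None,
                              noise_sd: float = 0.0) -> np.ndarray:
    """Random matrix with planted low-rank covariance structure.

    Columns of the rank-``latent_rank`` part have sample covariance with
    eigenvalue fractions exactly ``variance_fractions`` (equal by default)
    when ``noise_sd`` is 0: scores are exactly orthogonal zero-mean columns
    scaled to the requested variances, loadings are orthonormal.
    """
    if latent_rank > min(n - 1, p):
        raise ValueError(f"latent_rank {latent_rank} exceeds min(n-1, p) = {min(n - 1, p)}")
    if variance_fractions is None:
        variance_fractions = tuple(1.0 / latent_rank for _ in range(latent_rank))
    if len(variance_fractions) != latent_rank:
        raise ValueError("variance_fractions length must equal latent_rank")
    rng = np.random.default_rng(seed)
    S = rng.normal(size=(n, latent_rank))
    S = S - S.mean(axis=0)
    Q, _ = np.linalg.qr(S)             # orthonormal, zero-mean columns
    scores = Q * np.sqrt(np.array(variance_fractions) * (n - 1))
    L = rng.normal(size=(p, latent_rank))
    L, _ = np.linalg.qr(L)             # orthonormal loading columns
    X = scores @ L.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(n, p))
    return X


def write_fixture_files(out_dir, spec: FixtureSpec) -> None:
    """Write ils.csv, properties.csv and truth.json for a spec."""
    import pandas as pd
    from pathlib import Path
    from .chem_io import write_il_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, properties, truth = generate_reference_set(spec)
    write_il_table(records, out / "ils.csv")
    pd.DataFrame([{"il_id": p.il_id, "property": p.property,
                   "value": p.value, "units": p.units}
                  for p in properties]).to_csv(out / "properties.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
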