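"""Element data used by the weighted constitutional descriptors.

One versioned table holds, per element, the atomic mass, Sanderson
electronegativity, atomic polarizability, first ionization potential and
van der Waals volume.  Each property is also exposed scaled to the carbon
value, because the cumulative descriptors (Se, Sp, Si, Sv) and their means
(Me, Mp, Mi, Mv) sum carbon-scaled contributions over all atoms, hydrogens
included.

Sources: atomic masses are 2021 IUPAC standard atomic weights; Sanderson
electronegativities, polarizabilities (A^3) and first ionization potentials
(eV) follow the tabulations in Todeschini & Consonni, *Handbook of Molecular
Descriptors*; van der Waals volumes (A^3) are sphere volumes from Bondi-type
radii.  Formal charge never alters a lookup: these are composition scales,
so N+ weighs as N.
"""

from __future__ import annotations

from dataclasses import dataclass


ELEMENT_TABLE_VERSION = "ilpc-elements-v1"

#: symbol -> (mass /u, Sanderson EN, polarizability /A^3, first IP /eV, vdW volume /A^3)
_RAW: dict[str, tuple[float, float, float, float, float]] = {
    "H":  (1.008,   2.592, 0.667, 13.598,  6.709),
    "B":  (10.811,  2.275, 3.030,  8.298, 17.875),
    "C":  (12.011,  2.746, 1.760, 11.260, 22.449),
    "N":  (14.007,  3.194, 1.100, 14.534, 15.599),
    "O":  (15.999,  3.654, 0.802, 13.618, 11.494),
    "F":  (18.998,  4.000, 0.557, 17.423,  9.203),
    "P":  (30.974,  2.515, 3.630, 10.487, 24.429),
    "S":  (32.060,  2.957, 2.900, 10.360, 24.429),
    "Cl": (35.453,  3.475, 2.180, 12.968, 23.228),
    "Br": (79.904,  3.219, 3.050, 11.814, 31.059),
    "I":  (126.904, 2.778, 5.350, 10.451, 38.792),
}

_SCALES = ("mass", "electronegativity", "polarizability", "ionization", "vdw_volume")


class UnsupportedElementError(KeyError):
    """Raised when an atom's element has no entry in the element table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"element {symbol!r} is not covered by the element table "
                         f"({ELEMENT_TABLE_VERSION})")


@dataclass(frozen=True)
class ElementTable:
    """Per-element property table with carbon-scaled companions.

    ``value(symbol, scale)`` returns the raw value; ``carbon_scaled`` the
    ratio to carbon, which is exactly 1.0 for carbon on every scale.
    """

    version: str = ELEMENT_TABLE_VERSION

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(_RAW)

    @property
    def scales(self) -> tuple[str, ...]:
        return _SCALES

    def value(self, symbol: str, scale: str) -> float:
        try:
            row = _RAW[symbol]
        except KeyError:
            raise UnsupportedElementError(symbol) from None
        return row[_SCALES.index(scale)]

    def carbon_scaled(self, symbol: str, scale: str) -> float:
        return self.value(symbol, scale) / self.value("C", scale)

    def mass(self, symbol: str) -> float:
        return self.value(symbol, "mass")


DEFAULT_ELEMENT_TABLE = ElementTable()
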