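"""Property standardization, range-scale binning, and qualitative trend rules.

Measured property values are standardized within each property (z-scores,
population sd) and mapped onto a small number of colour bins — the range
scale used to paint the training map.  Viscosity, K_OW and solubility are
log-transformed before standardization because their raw scales are
heavy-tailed; enthalpy of fusion is standardized on its raw kJ/mol scale.

Qualitative prediction reads the map geometry.  With PC1 oriented along
overall ion size and PC2 along anion (heavy-atom) size, the trend rules are

    T_visc = +PC1 − PC2      viscosity rises with ion size, falls toward
                             the TFSI corner (high PC2)
    T_Kow  = +PC1            hydrophobicity tracks ion size
    T_sol  = −PC1 + PC2      water solubility runs opposite to K_OW, with a
                             secondary anion-size term
    T_dHf  = +PC2            enthalpy of fusion tracks anion size

Unit weights are a documented default; only the signs (and PC2's dominance
for the fusion enthalpy) are fixed by the underlying trend analysis.  An
IL's trend score is turned into an ordinal level (low / medium / high) by
its percentile against the training ILs' trend scores.  The fusion-enthalpy
answer additionally reports the cluster heuristic — TFSI-like cluster C is
high-prone, halide clusters A and F low-prone, the rest uncertain — with a
reduced-confidence note, and solubility answers for large-cation (PC1 > 0)
ILs carry a caveat flag because the anion-size term reverses there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PROPERTIES = ("viscosity", "Kow", "solubility", "enthalpy_of_fusion")
LOG_SCALED = ("viscosity", "Kow", "solubility")

DEFAULT_BIN_EDGES = (-1.5, -0.5, 0.5, 1.5)
BIN_LEVELS = ("very-low", "low", "medium", "high", "very-high")
BIN_COLORS = ("#2166ac", "#92c5de", "#f7f7f7", "#f4a582", "#b2182b")

#: trend-rule weights on (PC1, PC2); signs fixed by the map orientation
DEFAULT_TREND_WEIGHTS: dict[str, tuple[float, float]] = {
    "viscosity": (1.0, -1.0),
    "Kow": (1.0, 0.0),
    "solubility": (-1.0, 1.0),
    "enthalpy_of_fusion": (0.0, 1.0),
}

#: percentile cut points separating low / medium / high
DEFAULT_LEVEL_CUTS = (100.0 / 3.0, 200.0 / 3.0)

DHF_CLUSTER_HEURISTIC = {"C": "high-prone", "A": "low-prone", "F": "low-prone"}
DHF_CONFIDENCE_NOTE = ("fusion-enthalpy trends carry reduced confidence; "
                       "the cluster heuristic is the stronger signal")


@dataclass(frozen=True)
class PropertyRecord:
    il_id: str
    property: str
    value: float
    units: str = ""

    def __post_init__(self):
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}; "
                             f"expected one of {PROPERTIES}")
        if not math.isfinite(self.value):
            raise ValueError(f"{self.il_id}/{self.property}: non-finite value")


@dataclass(frozen=True)
class PropertyBin:
    z: float
    index: int
    level: str
    color: str


@dataclass(frozen=True)
class QualitativePrediction:
    il_id: str
    cluster: str
    levels: dict[str, str]          # property -> low / medium / high
    trend_scores: dict[str, float]
    rationale: dict[str, str]
    flags: tuple[str, ...] = ()


def standardize_property(values: np.ndarray, property: str | None = None,
                         log_transform: bool | None = None) -> np.ndarray:
    """z-scores within one property (population sd).

    ``log_transform`` defaults by property: natural log for viscosity, K_OW
    and solubility, identity for enthalpy of fusion.  Affine-equivalent
    inputs give identical z-scores.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite property value")
    if log_transform is None:
        log_transform = property in LOG_SCALED
    if log_transform:
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
    sd = x.std()  # population sd
    if sd == 0:
        raise ValueError("property values are constant; z-scores undefined")
    return (x - x.mean()) / sd


def bin_to_levels(z: float, edges: tuple[float, ...] = DEFAULT_BIN_EDGES) -> PropertyBin:
    """Range-scale bin for one standardized value.

    ``len(edges)+1`` half-open bins: bin i covers [edge_{i-1}, edge_i); a
    value equal to an edge belongs to the upper bin; values beyond the last
    edge fall in the last (closed) bin.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges_arr) <= 0):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    idx = int(np.searchsorted(edges_arr, z, side="right"))
    n_bins = len(edges_arr) + 1
    levels = BIN_LEVELS if n_bins == len(BIN_LEVELS) else tuple(
        f"bin-{i}" for i in range(n_bins))
    colors = BIN_COLORS if n_bins == len(BIN_COLORS) else ("#777777",) * n_bins
    return PropertyBin(z=float(z), index=idx, level=levels[idx], color=colors[idx])


def trend_scores(pc1: float, pc2: float,
                 weights: dict[str, tuple[float, float]] | None = None
                 ) -> dict[str, float]:
    """Per-property trend values from map coordinates."""
    w = DEFAULT_TREND_WEIGHTS if weights is None else weights
    return {prop: a * pc1 + b * pc2 for prop, (a, b) in w.items()}


def _level(score: float, training: np.ndarray,
           cuts: tuple[float, float] = DEFAULT_LEVEL_CUTS) -> str:
    pct = 100.0 * np.mean(np.asarray(training) <= score)
    if pct <= cuts[0]:
        return "low"
    if pct <= cuts[1]:
        return "medium"
    return "high"


def qualitative_predict(il_id: str, scores: dict[str, float],
                        training_trends: dict[str, np.ndarray],
                        cluster: str,
                        cuts: tuple[float, float] = DEFAULT_LEVEL_CUTS,
                        pc1: float | None = None) -> QualitativePrediction:
    """Ordinal levels by trend-score percentile against the training set."""
    levels: dict[str, str] = {}
    rationale: dict[str, str] = {}
    flags: list[str] = []
    for prop, score in scores.items():
        training = np.asarray(training_trends.get(prop, ()), dtype=float)
        if training.size == 0:
            raise ValueError(f"no training trend distribution for {prop!r}")
        levels[prop] = _level(score, training, cuts)
        rationale[prop] = (f"{prop}: trend score {score:.3g} is at the "
                           f"{100.0 * np.mean(training <= score):.0f}th percentile "
                           f"of the training map")
    if "enthalpy_of_fusion" in scores:
        tendency = DHF_CLUSTER_HEURISTIC.get(cluster, "uncertain")
        rationale["enthalpy_of_fusion"] += (
            f"; cluster {cluster} is {tendency} ({DHF_CONFIDENCE_NOTE})")
    if cluster == "C" and "viscosity" in scores:
        rationale["viscosity"] += ("; cluster C (TFSI-like anions) tends to the "
                                   "lowest viscosities on the map")
    if "solubility" in scores and pc1 is not None and pc1 > 0:
        flags.append("solubility-anion-trend-reverses-for-large-cations")
    return QualitativePrediction(il_id=il_id, cluster=cluster, levels=levels,
                                 trend_scores=dict(scores), rationale=rationale,
                                 flags=tuple(flags))
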