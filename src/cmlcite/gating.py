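"""Cytometry-style gating on scaled ADT values and capture-fraction reports.

CLR-normalized ADT values are transformed to a strictly positive "scale"
axis (antilog times 1000), mirroring the export convention used when moving
CITE-seq antibody data into gating software. Gates are conjunctions of
per-antibody +/− threshold terms; a + term requires the scaled value to
strictly exceed the threshold, a − term requires it not to, so the four
sign combinations over two markers always partition the cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import otsu_threshold

SCALE_FACTOR = 1000.0


@dataclass(frozen=True)
class GateTerm:
    antibody: str
    sign: str          # "+" or "-"
    threshold: float

    def __post_init__(self) -> None:
        if self.sign not in ("+", "-"):
            raise ValueError(f"gate sign must be '+' or '-', got {self.sign!r}")
        if self.threshold <= 0:
            raise ValueError("gate thresholds must be positive")


@dataclass
class GateDefinition:
    """AND-combination of per-antibody threshold terms."""

    terms: list[GateTerm]

    def __post_init__(self) -> None:
        names = [t.antibody for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("antibodies must be distinct within a gate")

    @classmethod
    def parse(cls, spec: dict[str, tuple[str, float]]) -> "GateDefinition":
        """Build from {antibody: (sign, threshold)}."""
        return cls([GateTerm(ab, s, t) for ab, (s, t) in spec.items()])


def adt_to_scale(clr: pd.DataFrame) -> pd.DataFrame:
    """Antilog of CLR values times the standard scaling factor of 1000."""
    values = clr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("CLR values must be finite")
    return pd.DataFrame(
        np.exp(values) * SCALE_FACTOR, index=clr.index, columns=clr.columns
    )


def auto_threshold(scaled: pd.DataFrame, antibody: str) -> float:
    """Automatic gate position: the Otsu cut of the scaled values."""
    cut = otsu_threshold(scaled[antibody].to_numpy())
    if cut is None:
        raise ValueError(f"no threshold found for {antibody!r} (constant values)")
    return cut


def apply_gate(scaled: pd.DataFrame, gate: GateDefinition) -> np.ndarray:
    """Boolean mask of cells passing every term of the gate."""
    missing = [t.antibody for t in gate.terms if t.antibody not in scaled.columns]
    if missing:
        raise ValueError(f"gate antibodies absent from table: {missing}")
    mask = np.ones(len(scaled), dtype=bool)
    for term in gate.terms:
        values = scaled[term.antibody].to_numpy()
        passes = values > term.threshold
        mask &= passes if term.sign == "+" else ~passes
    return mask


def combination_gates(
    marker_a: str, threshold_a: float, marker_b: str, threshold_b: float
) -> dict[str, GateDefinition]:
    """The four sign-combination gates over two markers (e.g. CD26/CD35)."""
    out = {}
    for sa in "+-":
        for sb in "+-":
            out[f"{marker_a}{sa}{marker_b}{sb}"] = GateDefinition(
                [GateTerm(marker_a, sa, threshold_a),
                 GateTerm(marker_b, sb, threshold_b)]
            )
    return out


def capture_fraction(mask: np.ndarray, population: np.ndarray) -> dict:
    """Fraction of a population captured by a gate.

    ``mask`` and ``population`` are boolean arrays over the same cells.
    An empty population yields a missing (None) fraction, never zero.
    """
    mask = np.asarray(mask, dtype=bool)
    population = np.asarray(population, dtype=bool)
    n_pop = int(population.sum())
    n_captured = int((mask & population).sum())
    fraction = n_captured / n_pop if n_pop else None
    return {"fraction": fraction, "n_captured": n_captured, "n_population": n_pop}


def capture_report(
    scaled: pd.DataFrame,
    gates: dict[str, GateDefinition],
    populations: dict[str, np.ndarray],
) -> pd.DataFrame:
    """(gate, population) capture-fraction table with denominators."""
    rows = []
    for gname, gate in gates.items():
        mask = apply_gate(scaled, gate)
        for pname, pop in populations.items():
            entry = capture_fraction(mask, pop)
            rows.append((gname, pname, entry["fraction"],
                         entry["n_captured"], entry["n_population"]))
    return pd.DataFrame(
        rows, columns=["gate", "population", "fraction", "n_captured",
                       "n_population"]
    )


def lsc_hsc_ratio(
    scaled: pd.DataFrame,
    cd26_threshold: float,
    cd35_threshold: float,
    compartment: np.ndarray,
    cd26: str = "CD26",
    cd35: str = "CD35",
) -> dict:
    """Ratio of CD26+CD35− (LSC-like) to CD26−CD35+ (HSC-like) cells within
    a compartment; the ratio is missing (None) when the denominator is 0."""
    compartment = np.asarray(compartment, dtype=bool)
    if compartment.sum() == 0:
        raise ValueError("compartment is empty")
    lsc_gate = GateDefinition(
        [GateTerm(cd26, "+", cd26_threshold), GateTerm(cd35, "-", cd35_threshold)]
    )
    hsc_gate = GateDefinition(
        [GateTerm(cd26, "-", cd26_threshold), GateTerm(cd35, "+", cd35_threshold)]
    )
    n_lsc = int((apply_gate(scaled, lsc_gate) & compartment).sum())
    n_hsc = int((apply_gate(scaled, hsc_gate) & compartment).sum())
    return {
        "n_lsc_like": n_lsc,
        "n_hsc_like": n_hsc,
        "ratio": n_lsc / n_hsc if n_hsc else None,
    }
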