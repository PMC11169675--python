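"""Small numeric reductions for the wet-lab readouts.

Four independent desk calculations accompany the sequence pipeline:

* pore-ring stoichiometry — from the measured inner diameter of the
  oligomeric ring and the ~2.1 nm combined width of each monomer's twin
  transmembrane beta-hairpins, estimate monomers per ring;
* FRET donor-quench correction — background-subtract the donor-plus-
  unlabelled (DU - U) and donor-plus-acceptor (DA - UA) emissions and
  express the corrected DA as a percentage of the corrected DU (100 = no
  quenching);
* kinetic-trace normalisation — scale carboxyfluorescein-release traces so
  the positive control reads 100 arbitrary units;
* propidium-iodide positivity — fraction of cells whose mean red-channel
  intensity is strictly above the imaging background (7498 a.u. default).

Rounding of the geometry estimates is half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_PI_BACKGROUND = 7498.0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class RingGeometry:
    """Measured pore-ring geometry: inner diameter and per-monomer twin
    transmembrane beta-hairpin width, both in nm."""

    inner_diameter: float
    hairpin_width: float = 2.1

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0 or self.hairpin_width <= 0:
            raise ValueError("ring geometry dimensions must be positive")


@dataclass(frozen=True)
class FretQuartet:
    """The four emissions of one FRET correction: donor+unlabelled (DU),
    unlabelled alone (U), donor+acceptor (DA), unlabelled+acceptor (UA)."""

    E_DU: float
    E_U: float
    E_DA: float
    E_UA: float


@dataclass(frozen=True)
class KineticTrace:
    """One marker-release kinetic trace plus its positive-control emission."""

    times: tuple[float, ...]
    emissions: tuple[float, ...]
    positive_control_emission: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.emissions):
            raise ValueError("times and emissions must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CellIntensityTable:
    """Per-cell mean red-channel intensities and the imaging background."""

    intensities: tuple[float, ...]
    background: float = DEFAULT_PI_BACKGROUND

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensities):
            raise ValueError("intensities must be non-negative")


def ring_circumference(inner_diameter: float) -> int:
    """Inner circumference pi*d in nm, rounded half away from zero."""
    if inner_diameter <= 0:
        raise ValueError("diameter must be positive")
    return _round_half_away(math.pi * inner_diameter)


def estimate_monomer_count(circumference: float, hairpin_width: float) -> int:
    """Monomers per ring: circumference / per-monomer hairpin width, rounded."""
    if circumference <= 0 or hairpin_width <= 0:
        raise ValueError("circumference and hairpin width must be positive")
    return _round_half_away(circumference / hairpin_width)


def fret_quench(q: FretQuartet) -> float:
    """Percent of donor emission retained after background correction.

    The unlabelled emission is subtracted from DU, the unlabelled+acceptor
    emission from DA; the corrected DU is set to 100 and the corrected DA
    expressed as a percentage of it. 100 means no quenching.
    """
    corrected_du = q.E_DU - q.E_U
    if corrected_du <= 0:
        raise ValueError("donor signal not above background")
    return 100.0 * (q.E_DA - q.E_UA) / corrected_du


def normalize_trace(t: KineticTrace) -> np.ndarray:
    """Scale emissions so the positive control reads 100 arbitrary units."""
    if t.positive_control_emission <= 0:
        raise ValueError("positive control emission must be positive")
    return np.asarray(t.emissions, dtype=float) * (
        100.0 / t.positive_control_emission
    )


def call_pi_positive(table: CellIntensityTable) -> float:
    """Fraction of cells strictly above the background intensity."""
    if not table.intensities:
        raise ValueError("cell intensity table is empty")
    positive = sum(1 for v in table.intensities if v > table.background)
    return positive / len(table.intensities)
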