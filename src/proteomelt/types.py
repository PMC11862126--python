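"""Core domain types shared across the pipeline.

The pipeline's unit of measurement is one TMT multiplex ("set"): a single
melt curve in which the ten reporter channels of one MS run correspond to
ten denaturation temperatures of the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CONDITIONS = ("vehicle", "drug")


@dataclass(frozen=True)
class TemperatureGrid:
    """Ordered temperature ladder (degrees C) with a reference channel.

    The reference channel is the lowest temperature; melt profiles are
    expressed relative to it (fraction non-denatured = 1 at the reference).
    """

    temperatures: tuple[float, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        object.__setattr__(self, "temperatures", temps)
        if len(temps) < 3:
            raise ValueError("temperature grid needs at least 3 points")
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly ascending")
        if self.reference_index != int(np.argmin(temps)):
            raise ValueError("reference_index must point at the minimum temperature")

    def __len__(self) -> int:
        return len(self.temperatures)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.temperatures, dtype=float)

    @classmethod
    def default(cls, n: int = 10, low: float = 37.0, high: float = 67.0) -> "TemperatureGrid":
        """Evenly spaced ladder spanning 37-67 degrees C (ten points)."""
        return cls(tuple(np.linspace(low, high, n)), 0)


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one melt-curve sample: cell line, treatment arm, replicate."""

    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )

    def __str__(self) -> str:  # stable id used in tables and set naming
        return f"{self.cell_line}_{self.condition}_r{self.replicate}"


@dataclass
class PeptideQuantRecord:
    """One peptide's reporter intensities across the temperature grid in one set.

    ``intensities`` holds raw (arbitrary-unit) reporter signals, NaN where the
    channel was not quantified.  ``gene_symbols`` may contain several genes for
    shared (ambiguous) peptides.
    """

    peptide_id: str
    sequence: str
    gene_symbols: frozenset
    sample_key: SampleKey
    set_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.gene_symbols = frozenset(self.gene_symbols)
        if not self.gene_symbols:
            raise ValueError(f"peptide {self.peptide_id}: gene_symbols empty")
        arr = np.asarray(self.intensities, dtype=float)
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"peptide {self.peptide_id}: negative intensity")
        self.intensities = arr

    @property
    def is_ambiguous(self) -> bool:
        return len(self.gene_symbols) > 1


@dataclass(frozen=True)
class ComplexSet:
    """A named gene set (e.g. one protein complex from a GMT database)."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex {self.name!r} has no members")


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic melt curve.

    f(T) = bottom + (top - bottom) / (1 + exp((T - tm) / scale))

    With ``scale > 0`` the curve decreases with temperature; ``tm`` is the
    inflection (melting point), where f(tm) = (top + bottom) / 2.
    """

    bottom: float
    top: float
    tm: float
    scale: float

    def __post_init__(self) -> None:
        vals = (self.bottom, self.top, self.tm, self.scale)
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite 4PL parameters")
        if not self.bottom < self.top:
            raise ValueError("4PL requires bottom < top")

    def as_array(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.tm, self.scale], float)


def validate_grid_length(grid: TemperatureGrid, values: Sequence[float], what: str) -> None:
    if len(values) != len(grid):
        raise ValueError(f"{what}: expected {len(grid)} channel values, got {len(values)}")
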