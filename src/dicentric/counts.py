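"""Dicentric count spectra: the raw unit of cytogenetic scoring.

A scored sample is summarised by the number of cells that carry exactly
``k`` dicentric chromosomes, for ``k = 0, 1, 2, ...``.  The total cell
count ``N`` and total dicentric count ``X`` are sufficient statistics for
the mean yield, while the full spectrum is needed for dispersion
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

from .errors import InputError


class DoseDefinition(str, Enum):
    """Dosimetric quantity in which a dose value is expressed."""

    AIR_KERMA = "air_kerma"
    DOSE_TO_WATER = "dose_to_water"
    DOSE_TO_BLOOD = "dose_to_blood"


class ScoringMode(str, Enum):
    """Manual metaphase-by-metaphase scoring vs software-assisted scoring."""

    MANUAL = "manual"
    SEMI_AUTOMATIC = "semi_automatic"


@dataclass(frozen=True)
class AberrationDistribution:
    """Per-cell dicentric count spectrum of one scored sample.

    Parameters
    ----------
    counts
        Mapping ``k -> number of cells with exactly k dicentrics``.
    dose
        Irradiation dose in Gy for calibration samples; ``None`` for
        blind samples whose dose is to be estimated.
    sample_id
        Optional identifier (e.g. the code of a blind sample).
    """

    counts: Mapping[int, int]
    dose: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        cleaned: dict[int, int] = {}
        for k, c in self.counts.items():
            ki, ci = int(k), int(c)
            if ki != k or ci != c:
                raise InputError(f"counts must be integer-valued, got {k}: {c}")
            if ki < 0 or ci < 0:
                raise InputError(f"counts must be non-negative, got {k}: {c}")
            if ci > 0 or ki == 0:
                cleaned[ki] = ci
        if not cleaned or sum(cleaned.values()) < 1:
            raise InputError("a distribution needs at least one scored cell")
        if self.dose is not None and self.dose < 0:
            raise InputError(f"dose must be >= 0, got {self.dose}")
        object.__setattr__(self, "counts", dict(sorted(cleaned.items())))

    # -- sufficient statistics -------------------------------------------------

    @property
    def n_cells(self) -> int:
        """Total number of scored cells, N."""
        return sum(self.counts.values())

    @property
    def total_dicentrics(self) -> int:
        """Total number of dicentrics over all cells, X."""
        return sum(k * c for k, c in self.counts.items())

    @property
    def mean_yield(self) -> float:
        """Observed dicentrics per cell, X / N."""
        return self.total_dicentrics / self.n_cells

    def spectrum(self) -> np.ndarray:
        """Dense spectrum ``[c_0, c_1, ..., c_kmax]``."""
        kmax = max(self.counts)
        out = np.zeros(kmax + 1, dtype=np.int64)
        for k, c in self.counts.items():
            out[k] = c
        return out

    def sample_variance(self) -> float:
        """Unbiased (N-1 denominator) variance of the per-cell counts."""
        n = self.n_cells
        if n < 2:
            raise InputError("variance needs at least 2 cells")
        mu = self.mean_yield
        ss = sum(c * (k - mu) ** 2 for k, c in self.counts.items())
        return ss / (n - 1)

    @classmethod
    def from_cells(
        cls,
        cells: np.ndarray,
        dose: float | None = None,
        sample_id: str | None = None,
    ) -> "AberrationDistribution":
        """Build a spectrum from an array of per-cell dicentric counts."""
        cells = np.asarray(cells, dtype=np.int64)
        if cells.size < 1:
            raise InputError("need at least one cell")
        if (cells < 0).any():
            raise InputError("per-cell counts must be non-negative")
        spectrum = np.bincount(cells)
        counts = {int(k): int(c) for k, c in enumerate(spectrum)}
        return cls(counts=counts, dose=dose, sample_id=sample_id)


def pool(distributions: list[AberrationDistribution]) -> dict[float, tuple[int, int]]:
    """Aggregate distributions by dose into ``{dose: (N, X)}`` totals."""
    agg: dict[float, tuple[int, int]] = {}
    for d in distributions:
        if d.dose is None:
            raise InputError("calibration distributions must carry a dose")
        n, x = agg.get(d.dose, (0, 0))
        agg[d.dose] = (n + d.n_cells, x + d.total_dicentrics)
    return dict(sorted(agg.items()))
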