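"""Poisson multiplicity-of-infection model for pooled lentiviral delivery.

Lentiviral infection of photoreceptors is modeled as a Poisson process with
mean m (the MOI).  The experimentally observed quantity is the labeling
fraction f — the fraction of cells infected by at least one virus — related
to the MOI by

    f = 1 - e^(-m)        m = -ln(1 - f)

so the full multiplicity distribution follows from f alone:

    P(k) = [-ln(1 - f)]^k / k! * (1 - f),   k = 0, 1, 2, ...

A retina is described as discrete regions with different labeling fractions
(infection falls off with distance from the injection site); the expected
number of infected and multi-infected cells follows by summing over regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln


def moi_from_fraction(f: float) -> float:
    """MOI m = -ln(1-f) from the labeling fraction f in [0, 1)."""
    if not 0.0 <= f < 1.0:
        raise ValueError(f"labeling fraction must be in [0, 1), got {f}")
    return float(-np.log1p(-f))


def fraction_from_moi(m: float) -> float:
    """Labeling fraction f = 1 - e^(-m) from the MOI m >= 0."""
    if m < 0:
        raise ValueError(f"MOI must be nonnegative, got {m}")
    return float(-np.expm1(-m))


def infection_pmf(f: float, k: int | np.ndarray) -> float | np.ndarray:
    """P(cell infected by exactly k viruses) given labeling fraction f.

    Evaluated in log space for large k to avoid factorial overflow.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer):
        raise ValueError("k must be a nonnegative integer")
    m = moi_from_fraction(f)
    if m == 0.0:
        out = np.where(k_arr == 0, 1.0, 0.0)
        return float(out) if np.isscalar(k) else out
    logp = k_arr * np.log(m) - gammaln(k_arr + 1) + np.log1p(-f)
    out = np.exp(logp)
    return float(out) if np.isscalar(k) else out


def multi_infection_fraction(f: float) -> float:
    """P(k >= 2) = 1 - (1-f) * (1 - ln(1-f)); 0 at f = 0, increasing in f."""
    m = moi_from_fraction(f)
    return float(1.0 - (1.0 - f) * (1.0 + m))


@dataclass(frozen=True)
class InfectionModel:
    """Poisson infection model pinned by the labeling fraction f."""

    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError("labeling fraction must be in [0, 1)")

    @classmethod
    def from_moi(cls, m: float) -> "InfectionModel":
        return cls(fraction_from_moi(m))

    @property
    def moi(self) -> float:
        return moi_from_fraction(self.f)

    def pmf(self, k: int | np.ndarray) -> float | np.ndarray:
        return infection_pmf(self.f, k)

    def multi_fraction(self) -> float:
        return multi_infection_fraction(self.f)


@dataclass(frozen=True)
class RegionalDesign:
    """Retina-wide design: total cells split across regions with distinct f.

    regions: sequence of (cell_fraction, labeling_fraction) pairs; the cell
    fractions must sum to 1.  Default total is 6.0e6 rods per retina — an
    explicit assumption (the rod count enters only this design calculation).
    """

    total_cells: float
    regions: tuple[tuple[float, float], ...]

    def __init__(
        self,
        total_cells: float = 6.0e6,
        regions: Sequence[tuple[float, float]] = ((0.5, 0.25), (0.5, 0.05)),
    ) -> None:
        object.__setattr__(self, "total_cells", float(total_cells))
        object.__setattr__(self, "regions", tuple((float(a), float(b)) for a, b in regions))
        if self.total_cells <= 0:
            raise ValueError("total_cells must be positive")
        if abs(sum(a for a, _ in self.regions) - 1.0) > 1e-9:
            raise ValueError("region cell fractions must sum to 1")
        for _, f in self.regions:
            if not 0.0 <= f < 1.0:
                raise ValueError("labeling fractions must be in [0, 1)")


def estimate_infected_cells(design: RegionalDesign) -> tuple[float, float]:
    """Expected (infected, multi-infected) cells across all regions.

    With the default design (6.0e6 rods, 50/50 split at f = 0.25 / 0.05) the
    expected infected count is 900,000.
    """
    infected = sum(
        design.total_cells * frac * f for frac, f in design.regions
    )
    multi = sum(
        design.total_cells * frac * multi_infection_fraction(f)
        for frac, f in design.regions
    )
    return float(infected), float(multi)


def cells_per_guide(design: RegionalDesign, library_size: int) -> float:
    """Expected infected cells per library guide (screen coverage)."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    infected, _ = estimate_infected_cells(design)
    return infected / library_size
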