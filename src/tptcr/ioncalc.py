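"""Charge-state arithmetic for native protein ions and low-resolution
intact-mass deconvolution from charge-reduced ion series.

In electrospray a protein of neutral mass ``M`` carrying ``z`` adducted
protons appears at ``m/z = M/z + m_p``. Proton-transfer charge reduction
(PTCR) strips protons without changing ``M``, so one species spreads over a
ladder of m/z values whose implied masses agree. Finding the consecutive
charge assignment that minimises the disagreement (the *mass spread*)
recovers the intact mass from two or more low-resolution peaks — no
isotope resolution required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from pyteomics import mass as _pmass

from .constants import DEFAULT_MAX_CHARGE, DEFAULT_SPREAD_BOUND, PROTON_MASS

__all__ = [
    "Species",
    "ChargeStateIon",
    "IonSeries",
    "DeconvolutionResult",
    "AmbiguityError",
    "NoSolutionError",
    "mz_from_mass",
    "mass_from_mz",
    "deconvolve_series",
    "series_consistency_score",
]


class AmbiguityError(ValueError):
    """A single peak cannot determine a charge assignment."""


class NoSolutionError(ValueError):
    """No charge assignment achieves an acceptable mass spread."""


@dataclass(frozen=True)
class Species:
    """A protein, protein-ligand complex, or ligand with a neutral mass.

    ``neutral_mass`` is the average (chemical) mass — the regime relevant to
    low-resolution native MS. A monoisotopic mass is carried optionally,
    mainly for small-molecule ligands. If an elemental formula is given the
    stored masses must agree with the formula-derived ones within 0.01 Da.
    """

    name: str
    neutral_mass: float
    monoisotopic_mass: float | None = None
    formula: str | None = None
    role: str = "protein"  # protein | complex | ligand

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral_mass must be positive, got {self.neutral_mass}")
        if self.role not in ("protein", "complex", "ligand"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.formula is not None:
            avg = _pmass.calculate_mass(formula=self.formula, average=True)
            if abs(avg - self.neutral_mass) > 0.01:
                raise ValueError(
                    f"{self.name}: stored neutral mass {self.neutral_mass} disagrees "
                    f"with formula average mass {avg:.4f} by more than 0.01 Da"
                )
            if self.monoisotopic_mass is not None:
                mono = _pmass.calculate_mass(formula=self.formula)
                if abs(mono - self.monoisotopic_mass) > 0.01:
                    raise ValueError(
                        f"{self.name}: stored monoisotopic mass disagrees with "
                        f"formula value {mono:.5f} by more than 0.01 Da"
                    )


@dataclass(frozen=True)
class ChargeStateIon:
    """One observed or predicted ion: an m/z value at an integer charge."""

    mz: float
    charge: int
    species_name: str | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.mz <= PROTON_MASS:
            raise ValueError(f"m/z must exceed the proton mass, got {self.mz}")

    @property
    def neutral_mass(self) -> float:
        return mass_from_mz(self.mz, self.charge)


@dataclass(frozen=True)
class IonSeries:
    """An ordered (descending-charge) series of ions of one species."""

    ions: tuple[ChargeStateIon, ...]
    implied_mass: float = field(init=False)
    mass_spread: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError("empty ion series")
        charges = [i.charge for i in self.ions]
        if any(b >= a for a, b in zip(charges, charges[1:])):
            raise ValueError("ion series charges must be strictly descending")
        masses = [i.neutral_mass for i in self.ions]
        object.__setattr__(self, "implied_mass", sum(masses) / len(masses))
        object.__setattr__(self, "mass_spread", max(masses) - min(masses))


@dataclass(frozen=True)
class DeconvolutionResult:
    mass: float
    charge_assignment: tuple[int, ...]
    spread: float
    n_peaks_used: int


def mz_from_mass(mass: float, charge: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of a species of neutral ``mass`` carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mass < 0:
        raise ValueError(f"mass must be non-negative, got {mass}")
    return mass / charge + proton_mass


def mass_from_mz(mz: float, charge: int, proton_mass: float = PROTON_MASS) -> float:
    """Neutral mass implied by an ion at ``mz`` with ``charge`` protons."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if mz < proton_mass:
        raise ValueError(f"m/z must be at least the proton mass {proton_mass}, got {mz}")
    return charge * (mz - proton_mass)


def series_consistency_score(
    peaks: Sequence[float],
    assignment: Sequence[int],
    proton_mass: float = PROTON_MASS,
) -> float:
    """Mass spread (max - min implied mass, Da) of a charge assignment.

    Zero for an exact ladder under the correct charges; large when the
    assignment is wrong — a wrong consecutive assignment shifts every implied
    mass by a different multiple of the peak m/z, so the spread explodes.
    """
    if len(peaks) != len(assignment):
        raise ValueError("peaks and assignment must have equal length")
    if any(z < 1 for z in assignment):
        raise ValueError("all charges must be >= 1")
    masses = [mass_from_mz(p, z, proton_mass) for p, z in zip(peaks, assignment)]
    return max(masses) - min(masses)


def _candidate_assignments(
    n: int, max_charge: int, require_consecutive: bool
) -> list[tuple[int, ...]]:
    # Peaks are ascending in m/z, so charges are descending.
    if require_consecutive:
        return [
            tuple(range(zmax, zmax - n, -1))
            for zmax in range(n, max_charge + 1)
        ]
    return [
        tuple(sorted(c, reverse=True))
        for c in combinations(range(1, max_charge + 1), n)
    ]


def deconvolve_series(
    peaks: Sequence[float],
    max_charge: int = DEFAULT_MAX_CHARGE,
    require_consecutive: bool = True,
    spread_bound: float = DEFAULT_SPREAD_BOUND,
    proton_mass: float = PROTON_MASS,
) -> DeconvolutionResult:
    """Recover an intact mass from a charge-reduced m/z ladder.

    Enumerates candidate charge assignments (consecutive descending integers
    when ``require_consecutive``, otherwise any strictly descending set up to
    ``max_charge``), scores each by the spread of the implied masses, and
    returns the assignment with minimal spread. Ties break toward the lowest
    maximum charge, then the lowest mass — deterministic.

    Parameters
    ----------
    peaks
        m/z values sorted ascending, at least two.
    max_charge
        Charge search ceiling (must be >= number of peaks).
    spread_bound
        Assignments whose spread exceeds this (Da) are rejected; if none
        survives, :class:`NoSolutionError` is raised.
    """
    peaks = list(peaks)
    if len(peaks) < 2:
        raise AmbiguityError(
            "a single peak admits every charge; supply >= 2 peaks or a charge hint"
        )
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("peaks must be sorted strictly ascending")
    if max_charge < len(peaks):
        raise ValueError("max_charge must be >= number of peaks")

    best: tuple[float, int, float, tuple[int, ...]] | None = None
    for assignment in _candidate_assignments(len(peaks), max_charge, require_consecutive):
        masses = [mass_from_mz(p, z, proton_mass) for p, z in zip(peaks, assignment)]
        spread = max(masses) - min(masses)
        mean = sum(masses) / len(masses)
        key = (spread, max(assignment), mean, assignment)
        if best is None or key < best:
            best = key
    assert best is not None
    spread, _, mean, assignment = best
    if spread > spread_bound:
        raise NoSolutionError(
            f"no charge assignment with mass spread <= {spread_bound} Da "
            f"(best: {spread:.3f} Da at charges {assignment})"
        )
    return DeconvolutionResult(
        mass=mean,
        charge_assignment=assignment,
        spread=spread,
        n_peaks_used=len(peaks),
    )
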