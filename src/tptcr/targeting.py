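"""Multiplexed tPTCR target tables, product-ladder prediction, and
MRM-like product matching.

Targeted PTCR works like multiple reaction monitoring for intact proteins:
a cohort of precursor ions is isolated (quadrupole multiplexing, which caps
precursor m/z at 2000), charge-reduced together, and each target is
confirmed — and imaged — from its *product* (charge-reduced) ions only, so
background ions overlapping the precursor never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .constants import (
    DEFAULT_MATCH_TOLERANCE,
    ION_TRAP_ISOLATION_CEILING,
    PROTON_MASS,
    QUADRUPOLE_ISOLATION_CEILING,
)
from .ioncalc import ChargeStateIon, mass_from_mz, mz_from_mass

__all__ = [
    "TargetEntry",
    "TargetTable",
    "ProductMatch",
    "MatchReport",
    "predict_ptcr_products",
    "validate_target_table",
    "match_products",
]


@dataclass(frozen=True)
class TargetEntry:
    """One multiplexed tPTCR target: a precursor and its product charge range."""

    species_name: str
    precursor_mz: float
    precursor_charge: int
    product_charges: tuple[int, ...]
    isolation_width: float = 4.0
    match_tolerance: float = DEFAULT_MATCH_TOLERANCE

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if not self.product_charges:
            raise ValueError("product_charges must be non-empty")
        zs = self.product_charges
        if any(b >= a for a, b in zip(zs, zs[1:])) or any(z < 1 for z in zs):
            raise ValueError("product_charges must be strictly descending and >= 1")
        if any(z >= self.precursor_charge for z in zs):
            raise ValueError("product charges must be below the precursor charge")
        if self.isolation_width <= 0 or self.match_tolerance <= 0:
            raise ValueError("isolation_width and match_tolerance must be positive")

    @property
    def neutral_mass(self) -> float:
        return mass_from_mz(self.precursor_mz, self.precursor_charge)

    def product_ions(self) -> list[ChargeStateIon]:
        return predict_ptcr_products(
            self.precursor_mz, self.precursor_charge, self.product_charges,
            species_name=self.species_name,
        )


@dataclass(frozen=True)
class TargetTable:
    entries: tuple[TargetEntry, ...]
    max_isolation_mz: float = QUADRUPOLE_ISOLATION_CEILING

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("target table must contain at least one entry")


@dataclass(frozen=True)
class ProductMatch:
    product_charge: int
    predicted_mz: float
    observed_mz: float | None
    intensity: float


@dataclass(frozen=True)
class MatchReport:
    """Per-entry confirmation report: which predicted products were observed."""

    entry: TargetEntry
    matches: tuple[ProductMatch, ...]
    n_matched: int = field(init=False)
    confirmed: bool = field(init=False)
    min_products: int = 2

    def __post_init__(self) -> None:
        n = sum(1 for m in self.matches if m.observed_mz is not None)
        object.__setattr__(self, "n_matched", n)
        object.__setattr__(self, "confirmed", n >= self.min_products)


def predict_ptcr_products(
    precursor_mz: float,
    precursor_charge: int,
    product_charges: Sequence[int],
    proton_mass: float = PROTON_MASS,
    species_name: str | None = None,
) -> list[ChargeStateIon]:
    """Predict the charge-reduced product ladder of a precursor.

    PTCR transfers protons to the reagent anion; the protein's neutral mass
    is conserved, so a product at charge z' sits at
    ``mz' = z*(mz - m_p)/z' + m_p``.
    """
    products = []
    for z in product_charges:
        if not 1 <= z < precursor_charge:
            raise ValueError(
                f"product charge {z} must lie in [1, {precursor_charge - 1}]"
            )
        neutral = mass_from_mz(precursor_mz, precursor_charge, proton_mass)
        products.append(
            ChargeStateIon(
                mz=mz_from_mass(neutral, z, proton_mass),
                charge=z,
                species_name=species_name,
            )
        )
    return products


Mode = Literal["quadrupole_multiplexed", "ion_trap_single"]


def validate_target_table(
    table: TargetTable,
    mode: Mode = "quadrupole_multiplexed",
    quadrupole_ceiling: float = QUADRUPOLE_ISOLATION_CEILING,
    ion_trap_ceiling: float = ION_TRAP_ISOLATION_CEILING,
) -> list[TargetEntry]:
    """Entries whose precursor m/z exceeds the isolation ceiling of ``mode``.

    Multiplexed precursor selection requires the quadrupole, whose upper
    isolation limit (2000 Th by default) is far below the ion trap's
    (8000 Th) — the practical constraint on which species can be multiplexed.
    An empty return value means the table is valid for the mode.
    """
    ceiling = {
        "quadrupole_multiplexed": quadrupole_ceiling,
        "ion_trap_single": ion_trap_ceiling,
    }[mode]
    return [e for e in table.entries if e.precursor_mz > ceiling]


def match_products(
    mz: np.ndarray | Sequence[float],
    intensity: np.ndarray | Sequence[float],
    entry: TargetEntry,
    min_products: int = 2,
) -> MatchReport:
    """Match a centroided spectrum against an entry's predicted product ladder.

    Each predicted product m/z is matched to the nearest centroid within
    ``entry.match_tolerance`` (ties: smallest |dm/z|, then higher intensity).
    Peaks inside the precursor isolation window are never counted, so
    interference at the precursor cannot produce a confirmation.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity arrays must have the same shape")

    half_iso = entry.isolation_width / 2.0
    in_precursor = np.abs(mz - entry.precursor_mz) <= half_iso
    usable = ~in_precursor

    matches: list[ProductMatch] = []
    for ion in entry.product_ions():
        best_idx: int | None = None
        if mz.size:
            d = np.abs(mz - ion.mz)
            ok = usable & (d <= entry.match_tolerance)
            if ok.any():
                idx = np.flatnonzero(ok)
                # smallest |dm/z| first, then higher intensity
                order = sorted(idx, key=lambda i: (d[i], -intensity[i]))
                best_idx = order[0]
        if best_idx is None:
            matches.append(ProductMatch(ion.charge, ion.mz, None, 0.0))
        else:
            matches.append(
                ProductMatch(
                    ion.charge, ion.mz,
                    float(mz[best_idx]), float(intensity[best_idx]),
                )
            )
    return MatchReport(entry=entry, matches=tuple(matches), min_products=min_products)
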