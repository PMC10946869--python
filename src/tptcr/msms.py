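"""HCD neutral-loss analysis for native protein-ligand complexes.

Collisional activation of a non-covalent [protein+ligand] complex can eject
the ligand as a neutral molecule: the product ion keeps the precursor's
charge and the mass difference equals the ligand mass (times the
stoichiometry). The ligand then does *not* appear in the low-m/z region —
the signature distinguishing neutral loss from charged-ligand dissociation.

Ligand masses are handled monoisotopically (sub-kDa molecules are isotope-
resolved even at modest resolving power) while protein masses remain in the
average-mass regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pyteomics import mass as _pmass

from .constants import ADDUCT_MASSES
from .ioncalc import ChargeStateIon, mass_from_mz

__all__ = [
    "LigandRecord",
    "LigandCandidate",
    "NeutralLossResult",
    "AdductMatch",
    "InconsistentPairError",
    "measure_neutral_loss",
    "identify_ligand",
    "detect_charged_ligand",
    "BEZAFIBRATE",
]


class InconsistentPairError(ValueError):
    """Product implied mass exceeds the precursor's beyond tolerance."""


@dataclass(frozen=True)
class LigandRecord:
    """A small-molecule ligand with formula-checked masses."""

    name: str
    formula: str
    monoisotopic_mass: float
    average_mass: float

    def __post_init__(self) -> None:
        mono = _pmass.calculate_mass(formula=self.formula)
        avg = _pmass.calculate_mass(formula=self.formula, average=True)
        if abs(mono - self.monoisotopic_mass) > 0.01:
            raise ValueError(
                f"{self.name}: monoisotopic mass {self.monoisotopic_mass} disagrees "
                f"with formula value {mono:.5f}"
            )
        if abs(avg - self.average_mass) > 0.01:
            raise ValueError(
                f"{self.name}: average mass {self.average_mass} disagrees "
                f"with formula value {avg:.5f}"
            )

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "LigandRecord":
        return cls(
            name=name,
            formula=formula,
            monoisotopic_mass=_pmass.calculate_mass(formula=formula),
            average_mass=_pmass.calculate_mass(formula=formula, average=True),
        )


#: The fibrate drug whose 1:1 complex with FABP1 motivates this package.
BEZAFIBRATE = LigandRecord.from_formula("bezafibrate", "C19H20ClNO4")


@dataclass(frozen=True)
class LigandCandidate:
    name: str
    mass_error: float
    stoichiometry: int


@dataclass(frozen=True)
class NeutralLossResult:
    delta_mass: float
    precursor_charge: int
    product_charge: int
    charge_retained: bool = field(init=False)
    ligand_candidates: tuple[LigandCandidate, ...] = ()
    stoichiometry: int | None = None

    def __post_init__(self) -> None:
        if self.delta_mass < 0:
            raise ValueError("delta_mass must be non-negative")
        object.__setattr__(
            self, "charge_retained", self.precursor_charge == self.product_charge
        )

    @property
    def delta_mass_nominal(self) -> int:
        """The loss rounded to the nearest Da (as printed on annotated spectra)."""
        return round(self.delta_mass)


def measure_neutral_loss(
    precursor: ChargeStateIon,
    product: ChargeStateIon,
    tolerance: float = 2.0,
) -> NeutralLossResult:
    """Mass difference between a precursor and a charge-retaining product.

    ``delta = z_pre*(mz_pre - m_p) - z_prod*(mz_prod - m_p)``. A product whose
    implied mass exceeds the precursor's by more than ``tolerance`` Da is an
    inconsistent pair (the roles are swapped), not a negative loss. A pure
    charge-reduction product (lower charge, same mass) gives delta ~ 0 with
    ``charge_retained`` False.
    """
    if product.charge > precursor.charge:
        raise InconsistentPairError(
            f"product charge {product.charge} exceeds precursor charge "
            f"{precursor.charge}"
        )
    delta = mass_from_mz(precursor.mz, precursor.charge) - mass_from_mz(
        product.mz, product.charge
    )
    if delta < -tolerance:
        raise InconsistentPairError(
            f"product implied mass exceeds precursor's by {-delta:.2f} Da; "
            "precursor/product roles are inconsistent"
        )
    return NeutralLossResult(
        delta_mass=round(max(delta, 0.0), 2),
        precursor_charge=precursor.charge,
        product_charge=product.charge,
    )


def identify_ligand(
    delta_mass: float,
    library: Sequence[LigandRecord],
    tolerance: float = 0.5,
    k_max: int = 3,
    use_monoisotopic: bool = True,
) -> list[LigandCandidate]:
    """Rank library ligands against a neutral-loss mass.

    A candidate matches when ``|delta - k*mass_L| <= tolerance`` for some
    stoichiometry ``k in 1..k_max``. Candidates are ranked by absolute mass
    error, then by smaller k. An empty list means no ligand explains the
    loss — not an error.
    """
    if not library:
        raise ValueError("ligand library must be non-empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    out: list[LigandCandidate] = []
    for lig in library:
        m = lig.monoisotopic_mass if use_monoisotopic else lig.average_mass
        for k in range(1, k_max + 1):
            err = delta_mass - k * m
            if abs(err) <= tolerance:
                out.append(LigandCandidate(lig.name, err, k))
    out.sort(key=lambda c: (abs(c.mass_error), c.stoichiometry))
    return out


@dataclass(frozen=True)
class AdductMatch:
    ligand: str
    adduct: str
    predicted_mz: float
    observed_mz: float
    intensity: float


def detect_charged_ligand(
    mz: np.ndarray | Sequence[float],
    intensity: np.ndarray | Sequence[float],
    library: Sequence[LigandRecord],
    low_mz_window: tuple[float, float] = (100.0, 1000.0),
    tolerance: float = 0.5,
    adducts: dict[str, float] | None = None,
) -> list[AdductMatch]:
    """Search the low-m/z region for charged ligand ions ([L+H]+/[L+Na]+/[L+K]+).

    A neutral-loss-only HCD spectrum returns an empty list; full-scan spectra
    of dosed tissue typically show the protonated/sodiated/potassiated drug.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    adducts = ADDUCT_MASSES if adducts is None else adducts
    lo, hi = low_mz_window
    matches: list[AdductMatch] = []
    for lig in library:
        for label, amass in adducts.items():
            pred = lig.monoisotopic_mass + amass
            if not lo <= pred <= hi:
                continue
            if mz.size == 0:
                continue
            d = np.abs(mz - pred)
            i = int(np.argmin(d))
            if d[i] <= tolerance:
                matches.append(
                    AdductMatch(
                        lig.name, f"[L+{label}]+", pred,
                        float(mz[i]), float(intensity[i]),
                    )
                )
    return matches
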