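"""Synthetic instrument and tissue simulator.

Stands in for the dosed animals and the mass spectrometer: a tissue phantom
(bulk parenchyma crossed by a blood vessel) carries per-pixel abundances of
a species panel; a spectral model renders native spectra with charge-state
envelopes, Gaussian peak shapes and counting-like noise; PTCR and HCD act on
ion populations; a line-scan acquisition sweeps the phantom row by row.

Default panel (a liver-like scene):

* free FABP1 (~14.3 kDa) and ACBP (~10 kDa) in bulk tissue,
* the [FABP1+drug] complex in bulk tissue, scaled by scenario
  (2 h post-dose > 6 h post-dose > control = 0),
* heme-bound alpha-globin (~15.8 kDa) confined to the vessel.

All randomness flows from explicit seeds; identical seeds give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .ioncalc import Species, mz_from_mass
from .msms import BEZAFIBRATE, LigandRecord
from .targeting import TargetEntry, TargetTable, predict_ptcr_products

__all__ = [
    "Phantom",
    "SpectralModel",
    "ScenarioConfig",
    "Spectrum",
    "LineScanDataset",
    "REGION_BACKGROUND",
    "REGION_BULK",
    "REGION_VESSEL",
    "default_species_panel",
    "default_target_table",
    "make_phantom",
    "render_spectrum",
    "apply_ptcr",
    "apply_hcd",
    "acquire_line_scans",
]

REGION_BACKGROUND, REGION_BULK, REGION_VESSEL = 0, 1, 2
REGION_NAMES = {REGION_BACKGROUND: "background", REGION_BULK: "bulk_tissue",
                REGION_VESSEL: "vessel"}

# Intact masses (Da, average regime). The complex and globin masses are the
# values recovered by deconvolving their 7+/6+ charge-reduced product pairs;
# free FABP1 is the complex minus the monoisotopic drug mass. The ACBP mass
# is a synthetic ~10 kDa placeholder (its true value is not constrained here).
COMPLEX_MASS = 14675.40
FABP1_MASS = COMPLEX_MASS - BEZAFIBRATE.monoisotopic_mass
GLOBIN_MASS = 15812.00
ACBP_MASS = 9955.60


def default_species_panel() -> list[Species]:
    return [
        Species("FABP1", FABP1_MASS, role="protein"),
        Species("FABP1+bezafibrate", COMPLEX_MASS, role="complex"),
        Species("heme-alpha-globin", GLOBIN_MASS, role="protein"),
        Species("ACBP", ACBP_MASS, role="protein"),
    ]


def default_target_table() -> TargetTable:
    """Multiplexed tPTCR targets: 8+/8+/8+/6+ precursors, 7+ and 6+ (or 5+/4+)
    products. A reconstruction of the published multiplexing scheme from the
    species list; precursor m/z values derive from the panel masses."""
    def entry(name: str, mass: float, z: int, products: tuple[int, ...]) -> TargetEntry:
        return TargetEntry(
            species_name=name,
            precursor_mz=round(mz_from_mass(mass, z), 2),
            precursor_charge=z,
            product_charges=products,
        )

    return TargetTable(entries=(
        entry("FABP1", FABP1_MASS, 8, (7, 6)),
        entry("FABP1+bezafibrate", COMPLEX_MASS, 8, (7, 6)),
        entry("heme-alpha-globin", GLOBIN_MASS, 8, (7, 6)),
        entry("ACBP", ACBP_MASS, 6, (5, 4)),
    ))


@dataclass(frozen=True)
class ScenarioConfig:
    """Dosing scenario: how strongly the complex is present.

    The 2 h > 6 h ordering mirrors rapid drug clearance; the control carries
    no complex at all. Scales are synthetic choices, not fitted quantities.
    """

    scenario: Literal["control", "dosed_2h", "dosed_6h"] = "dosed_2h"
    complex_abundance_scales: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.0, "dosed_2h": 1.0, "dosed_6h": 0.3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.complex_abundance_scales
        if s["control"] != 0.0:
            raise ValueError("control complex scale must be 0")
        if not s["dosed_2h"] > s["dosed_6h"] > 0:
            raise ValueError("require dosed_2h scale > dosed_6h scale > 0")

    @property
    def complex_scale(self) -> float:
        return self.complex_abundance_scales[self.scenario]


@dataclass(frozen=True)
class Phantom:
    """A tissue phantom: region labels plus per-species abundance maps."""

    region_mask: np.ndarray  # (h, w) int labels
    abundance_maps: dict[str, np.ndarray]  # species name -> (h, w) floats

    def __post_init__(self) -> None:
        for name, m in self.abundance_maps.items():
            if m.shape != self.region_mask.shape:
                raise ValueError(f"map {name!r} shape differs from mask")
            if (m < 0).any():
                raise ValueError(f"map {name!r} has negative abundances")
            if (m[self.region_mask == REGION_BACKGROUND] != 0).any():
                raise ValueError(f"map {name!r} nonzero on background")

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_mask.shape

    def abundances_at(self, y: int, x: int) -> dict[str, float]:
        return {k: float(v[y, x]) for k, v in self.abundance_maps.items()}


def make_phantom(
    width: int = 16,
    height: int = 16,
    vessel_geometry: Mapping | None = None,
    species_panel: Sequence[Species] | None = None,
    scenario: ScenarioConfig | None = None,
    background_margin: int = 1,
    base_abundance: float = 100.0,
    heterogeneity: float = 0.1,
) -> Phantom:
    """Build a liver-like phantom: bulk tissue with an embedded blood vessel.

    Free protein and complex live in the bulk only; heme-bound globin only in
    the vessel. The complex map is scaled by the scenario (zero for control).
    Per-pixel abundances get mild multiplicative heterogeneity (lognormal-ish,
    deterministic given the scenario seed).

    ``vessel_geometry``: ``{"shape": "disk", "center": (x, y), "radius": r}``
    (default: a disk of radius ~1/5 frame in the upper-left quadrant).
    """
    scenario = scenario or ScenarioConfig()
    panel = list(species_panel) if species_panel is not None else default_species_panel()
    if not panel:
        raise ValueError("species panel must be non-empty")
    if vessel_geometry is None:
        r0 = max(1.0, min(width, height) * 0.18)
        vessel_geometry = {
            "shape": "disk",
            "center": (max(r0, width * 0.3), max(r0, height * 0.3)),
            "radius": r0,
        }

    mask = np.full((height, width), REGION_BULK, dtype=np.int8)
    m = background_margin
    if m > 0:
        mask[:m, :] = REGION_BACKGROUND
        mask[-m:, :] = REGION_BACKGROUND
        mask[:, :m] = REGION_BACKGROUND
        mask[:, -m:] = REGION_BACKGROUND

    if vessel_geometry["shape"] != "disk":
        raise ValueError(f"unsupported vessel shape {vessel_geometry['shape']!r}")
    cx, cy = vessel_geometry["center"]
    r = vessel_geometry["radius"]
    if not (r <= cx <= width - r and r <= cy <= height - r):
        raise ValueError("vessel geometry does not fit in the frame")
    yy, xx = np.mgrid[0:height, 0:width]
    vessel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    mask[vessel & (mask != REGION_BACKGROUND)] = REGION_VESSEL

    rng = np.random.default_rng(scenario.seed)
    bulk = (mask == REGION_BULK).astype(float)
    ves = (mask == REGION_VESSEL).astype(float)

    def textured(base: np.ndarray, scale: float) -> np.ndarray:
        tex = np.exp(rng.normal(0.0, heterogeneity, size=base.shape))
        return base * scale * base_abundance * tex

    maps: dict[str, np.ndarray] = {}
    for sp in panel:
        if sp.role == "complex":
            maps[sp.name] = textured(bulk, scenario.complex_scale)
        elif "globin" in sp.name.lower():
            maps[sp.name] = textured(ves, 1.0)
        else:
            maps[sp.name] = textured(bulk, 1.0)
    return Phantom(region_mask=mask, abundance_maps=maps)


@dataclass(frozen=True)
class SpectralModel:
    """Peak-shape and noise model behind every rendered spectrum.

    Peaks are Gaussians with FWHM = m/z / resolving_power; peak area is
    abundance x envelope weight x accumulation. Additive noise has standard
    deviation ``noise_floor + shot_noise_scale*sqrt(signal)`` per channel — a
    tractable stand-in for counting statistics, so replicate-to-replicate
    SNR of an accumulated peak grows as sqrt(accumulation) once the shot
    term dominates.
    """

    resolving_power: float = 1000.0
    charge_envelopes: Mapping[str, Mapping[int, float]] = field(
        default_factory=dict
    )
    noise_floor: float = 0.5
    shot_noise_scale: float = 2.0
    grid_step: float = 0.1
    centroid_snr_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.resolving_power <= 0:
            raise ValueError("resolving_power must be positive")
        for name, env in self.charge_envelopes.items():
            w = np.array(list(env.values()), dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    f"envelope weights for {name!r} must be non-negative and sum to 1"
                )

    def envelope_for(self, species: Species) -> dict[int, float]:
        if species.name in self.charge_envelopes:
            return dict(self.charge_envelopes[species.name])
        # Default native envelope for 10-16 kDa proteins: charges 6-9 peaked
        # at 8+ (at 7+ for sub-12 kDa species like ACBP).
        if species.neutral_mass < 12000:
            return {8: 0.1, 7: 0.5, 6: 0.3, 5: 0.1}
        return {9: 0.1, 8: 0.5, 7: 0.3, 6: 0.1}


@dataclass(frozen=True)
class Spectrum:
    """m/z-intensity arrays with acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"  # profile | centroid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal shapes")


@dataclass(frozen=True)
class LineScanDataset:
    """Row-major line scans over a phantom: one spectrum per pixel."""

    spectra: tuple[Spectrum, ...]
    coordinates: tuple[tuple[int, int], ...]  # (x, y), x along scan direction
    shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.coordinates):
            raise ValueError("one coordinate per spectrum required")

    def spectrum_at(self, x: int, y: int) -> Spectrum:
        return self.spectra[y * self.shape[1] + x]


def _population_from_abundances(
    species_abundances: Mapping[Species, float] | Mapping[str, float],
    model: SpectralModel,
    panel: Sequence[Species] | None = None,
) -> dict[tuple[str, int], tuple[float, float]]:
    """Expand species abundances into {(name, z): (mz, abundance)} via envelopes."""
    if panel is not None:
        by_name = {s.name: s for s in panel}
        items = [(by_name[k], v) for k, v in species_abundances.items()]
    else:
        items = list(species_abundances.items())  # keys are Species
    pop: dict[tuple[str, int], tuple[float, float]] = {}
    for sp, ab in items:
        if ab <= 0:
            continue
        for z, w in model.envelope_for(sp).items():
            if w <= 0:
                continue
            pop[(sp.name, z)] = (mz_from_mass(sp.neutral_mass, z), ab * w)
    return pop


def render_spectrum(
    species_abundances: Mapping[Species, float],
    model: SpectralModel,
    mz_range: tuple[float, float],
    mode: str = "profile",
    accumulation: int = 1,
    seed: int | np.random.Generator = 0,
    population: Mapping[tuple[float, int], float] | None = None,
) -> Spectrum:
    """Render a native spectrum from species abundances (or a raw population).

    ``mode``: "full"/"profile" render the whole range in profile;
    "SIM" is profile over a (narrow) range with the given accumulation;
    "centroid" renders profile then picks local maxima above
    ``centroid_snr_threshold x noise_floor`` and reports intensity-weighted
    centroid m/z.

    ``population`` bypasses the envelope expansion: a mapping
    ``(mz, charge) -> abundance`` (used after PTCR/HCD processing).
    """
    lo, hi = mz_range
    if hi <= lo:
        raise ValueError("invalid m/z range")
    if accumulation < 1:
        raise ValueError("accumulation must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    grid = np.arange(lo, hi + model.grid_step / 2, model.grid_step)
    signal = np.zeros_like(grid)

    if population is None:
        pop = _population_from_abundances(species_abundances, model)
        peaks = [(mz, ab) for (_, _), (mz, ab) in pop.items()]
    else:
        peaks = [(mz, ab) for (mz, _), ab in population.items()]

    for mz0, ab in peaks:
        if not lo <= mz0 <= hi or ab <= 0:
            continue
        fwhm = mz0 / model.resolving_power
        sigma = fwhm / 2.3548200450309493
        area = ab * accumulation
        window = np.abs(grid - mz0) < 5 * sigma
        signal[window] += (
            area / (sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((grid[window] - mz0) / sigma) ** 2)
        )

    # additive noise, deliberately unclipped: a zero-mean baseline keeps
    # window integrals unbiased (clipping would bias low-signal regions up)
    sigma_noise = model.noise_floor + model.shot_noise_scale * np.sqrt(signal)
    intensity = signal + rng.normal(0.0, 1.0, size=grid.shape) * sigma_noise

    meta = {"mode": mode, "accumulation": accumulation, "mz_range": (lo, hi)}
    if mode in ("full", "profile", "SIM"):
        return Spectrum(grid, intensity, mode="profile", metadata=meta)
    if mode == "centroid":
        return _centroid(grid, intensity, model, meta)
    raise ValueError(f"unknown render mode {mode!r}")


def _centroid(grid: np.ndarray, intensity: np.ndarray,
              model: SpectralModel, meta: dict) -> Spectrum:
    threshold = model.centroid_snr_threshold * model.noise_floor
    # minimum separation: about one FWHM at the low end of the range
    fwhm_pts = (grid[0] / model.resolving_power) / model.grid_step
    idx, _ = find_peaks(intensity, height=threshold,
                        distance=max(3, int(round(fwhm_pts))))
    half = max(5, int(round(fwhm_pts / 2)))  # centroid window ~ +/- FWHM/2
    cmz, cint = [], []
    for i in idx:
        sl = slice(max(0, i - half), min(len(grid), i + half + 1))
        w = np.maximum(intensity[sl], 0.0)
        cmz.append(float(np.average(grid[sl], weights=w)))
        cint.append(float(w.sum()))
    return Spectrum(np.array(cmz), np.array(cint), mode="centroid", metadata=meta)


def estimate_snr(spectra: Sequence[Spectrum], mz0: float) -> float:
    """Empirical SNR of a peak from replicate profile spectra.

    Uses the grid channel nearest ``mz0``: SNR = mean / std of that channel's
    intensity across replicates. With the counting-like noise model the
    replicate std at the apex equals the per-channel noise there, so this is
    the apex signal-to-noise ratio.
    """
    if len(spectra) < 3:
        raise ValueError("need >= 3 replicates")
    i = int(np.argmin(np.abs(spectra[0].mz - mz0)))
    vals = np.array([s.intensity[i] for s in spectra])
    return float(vals.mean() / vals.std(ddof=1))


def apply_ptcr(
    population: Mapping[tuple[float, int], float],
    reaction_extent: float = 0.5,
    max_reductions: int = 2,
    seed: int = 0,
) -> dict[tuple[float, int], float]:
    """Charge-reduce an ion population by proton transfer.

    Each precursor of charge z is redistributed over charges z-k,
    k = 0..max_reductions, with truncated-geometric weights
    ``(1-p) p^k`` renormalised (p = reaction_extent). Total ion population is
    conserved exactly; product m/z follows the mass-conserving ladder.
    The redistribution is the expected (deterministic) one; ``seed`` is
    accepted for interface symmetry.
    """
    if not 0 <= reaction_extent < 1:
        raise ValueError("reaction_extent must be in [0, 1)")
    out: dict[tuple[float, int], float] = {}
    for (mz, z), ab in population.items():
        kmax = min(max_reductions, z - 1)
        raw = np.array([(1 - reaction_extent) * reaction_extent**k
                        for k in range(kmax + 1)])
        weights = raw / raw.sum()
        for k, w in enumerate(weights):
            if w <= 0:
                continue
            if k == 0:
                key = (mz, z)
            else:
                prod = predict_ptcr_products(mz, z, [z - k])[0]
                key = (prod.mz, prod.charge)
            out[key] = out.get(key, 0.0) + ab * float(w)
    return out


def apply_hcd(
    population: Mapping[tuple[float, int], float],
    dissociation_efficiency: float,
    ligand: LigandRecord | float = BEZAFIBRATE,
    complex_mz: float | None = None,
    seed: int = 0,
) -> dict[tuple[float, int], float]:
    """Dissociate a complex population by neutral ligand loss.

    A fraction ``dissociation_efficiency`` of each ion converts to the free
    protein at the SAME charge — the ligand leaves as a neutral molecule and
    never appears as an ion. The remainder survives intact. Population is
    conserved. If ``complex_mz`` is given, only ions at that m/z dissociate.
    ``ligand`` may be a :class:`~tptcr.msms.LigandRecord` (monoisotopic mass
    used) or a bare neutral-loss mass in Da.
    """
    if not 0 <= dissociation_efficiency <= 1:
        raise ValueError("dissociation_efficiency must be in [0, 1]")
    ligand_mass = ligand if isinstance(ligand, (int, float)) \
        else ligand.monoisotopic_mass
    out: dict[tuple[float, int], float] = {}
    for (mz, z), ab in population.items():
        if complex_mz is not None and abs(mz - complex_mz) > 1e-6:
            out[(mz, z)] = out.get((mz, z), 0.0) + ab
            continue
        surv = ab * (1 - dissociation_efficiency)
        diss = ab * dissociation_efficiency
        if surv > 0:
            out[(mz, z)] = out.get((mz, z), 0.0) + surv
        if diss > 0:
            free_mz = mz - ligand_mass / z
            key = (free_mz, z)
            out[key] = out.get(key, 0.0) + diss
    return out


def acquire_line_scans(
    phantom: Phantom,
    model: SpectralModel,
    target_table: TargetTable | None = None,
    mz_range: tuple[float, float] = (1500.0, 3000.0),
    mode: str = "profile",
    reaction_extent: float = 0.5,
    max_reductions: int = 2,
    species_panel: Sequence[Species] | None = None,
    seed: int = 0,
) -> LineScanDataset:
    """Sweep the phantom row by row (constant direction) and acquire one
    spectrum per pixel.

    With a ``target_table`` (tPTCR mode) each pixel's spectrum is the
    PTCR-processed multiplexed-target population: only the listed precursors
    are isolated, the whole cohort is charge-reduced together, and the
    resulting profile spectrum contains precursor remnants plus product
    ladders. Without a table, a full-scan native spectrum is rendered.
    """
    panel = list(species_panel) if species_panel is not None else default_species_panel()
    by_name = {s.name: s for s in panel}
    h, w = phantom.shape
    master = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    coords: list[tuple[int, int]] = []
    for y in range(h):
        for x in range(w):
            rng = np.random.default_rng(master.integers(0, 2**31))
            ab = phantom.abundances_at(y, x)
            if target_table is None:
                sp_ab = {by_name[n]: a for n, a in ab.items() if n in by_name}
                spec = render_spectrum(sp_ab, model, mz_range, mode=mode, seed=rng)
            else:
                pop: dict[tuple[float, int], float] = {}
                for entry in target_table.entries:
                    a = ab.get(entry.species_name, 0.0)
                    if a <= 0:
                        continue
                    # isolation keeps only the targeted precursor charge state
                    sp = by_name.get(entry.species_name)
                    env_w = model.envelope_for(sp).get(entry.precursor_charge, 0.0) \
                        if sp is not None else 1.0
                    if env_w <= 0:
                        continue
                    pop[(entry.precursor_mz, entry.precursor_charge)] = a * env_w
                pop = apply_ptcr(pop, reaction_extent, max_reductions)
                spec = render_spectrum(
                    {}, model, mz_range, mode=mode, seed=rng, population=pop
                )
            spectra.append(spec)
            coords.append((x, y))
    return LineScanDataset(tuple(spectra), tuple(coords), (h, w))
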