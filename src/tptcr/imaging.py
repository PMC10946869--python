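"""Ion-image extraction from line-scan datasets under the product-ion-only
rule, plus normalization, two-color composites, and region statistics.

The tPTCR imaging rule: a target's image is built solely from its
charge-reduced product ions. Signal at the precursor m/z — including any
background interferent that co-isolates with it — contributes nothing to
the image, which is what gives the method its specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .simulate import (
    REGION_NAMES,
    LineScanDataset,
    Spectrum,
)
from .targeting import TargetEntry

__all__ = [
    "IonImage",
    "CompositeImage",
    "extract_ion_image",
    "normalize_image",
    "compose",
    "region_statistics",
    "tic_image",
]


@dataclass(frozen=True)
class IonImage:
    """2-D intensity map for one target, product-ion channels only."""

    values: np.ndarray  # (h, w), non-negative
    target: TargetEntry | None = None
    channels_used: tuple[int, ...] = ()
    normalization: str = "none"  # none | TIC | max

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("ion image values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CompositeImage:
    """Multi-channel overlay; each channel max-scaled to [0, 1] independently."""

    channel_images: dict[str, IonImage]
    rgb: np.ndarray = field(init=False)

    _COLORS = {
        "red": (1.0, 0.0, 0.0),
        "green": (0.0, 1.0, 0.0),
        "blue": (0.0, 0.0, 1.0),
        "cyan": (0.0, 1.0, 1.0),
        "magenta": (1.0, 0.0, 1.0),
        "yellow": (1.0, 1.0, 0.0),
    }

    def __post_init__(self) -> None:
        if not self.channel_images:
            raise ValueError("at least one channel required")
        shapes = {im.shape for im in self.channel_images.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        h, w = shapes.pop()
        rgb = np.zeros((h, w, 3))
        for color, image in self.channel_images.items():
            if color not in self._COLORS:
                raise ValueError(f"unknown channel color {color!r}")
            v = image.values
            scaled = v / v.max() if v.max() > 0 else v
            for c, weight in enumerate(self._COLORS[color]):
                rgb[:, :, c] += weight * scaled
        np.clip(rgb, 0.0, 1.0, out=rgb)
        object.__setattr__(self, "rgb", rgb)

    def scaled_channel(self, color: str) -> np.ndarray:
        v = self.channel_images[color].values
        return v / v.max() if v.max() > 0 else v.copy()


def _window_signal(spec: Spectrum, center: float, tol: float) -> float:
    """Integrated signal within +/- tol of center (trapezoid for profile,
    plain sum for centroided data)."""
    sel = np.abs(spec.mz - center) <= tol
    if not sel.any():
        return 0.0
    if spec.mode == "centroid":
        return float(spec.intensity[sel].sum())
    return float(np.trapezoid(spec.intensity[sel], spec.mz[sel]))


def extract_ion_image(dataset: LineScanDataset, entry: TargetEntry) -> IonImage:
    """Extract a product-ion-only image for one target.

    Per pixel: the sum over the entry's product charges of the signal
    integrated within ``+/- match_tolerance`` of each predicted product m/z.
    The precursor m/z is not among the extraction windows, so precursor-window
    interference cannot alter any pixel. Raster: row 0 is the first acquired
    line; x increases along the scan direction.
    """
    if not entry.product_charges:
        raise ValueError("entry has no product charges")
    h, w = dataset.shape
    values = np.zeros((h, w))
    products = entry.product_ions()
    for spec, (x, y) in zip(dataset.spectra, dataset.coordinates):
        values[y, x] = sum(
            _window_signal(spec, ion.mz, entry.match_tolerance) for ion in products
        )
    # noise can integrate slightly negative on empty pixels; images are
    # non-negative by contract
    np.maximum(values, 0.0, out=values)
    return IonImage(values=values, target=entry,
                    channels_used=entry.product_charges)


def tic_image(dataset: LineScanDataset) -> np.ndarray:
    """Per-pixel total ion current (sum of all intensities)."""
    h, w = dataset.shape
    tic = np.zeros((h, w))
    for spec, (x, y) in zip(dataset.spectra, dataset.coordinates):
        tic[y, x] = float(spec.intensity.sum())
    return tic


def normalize_image(
    image: IonImage,
    mode: str = "none",
    per_pixel_tic: np.ndarray | None = None,
) -> IonImage:
    """Return a normalized copy: none (identity), TIC (per-pixel division,
    0/0 -> 0), or max (division by the image maximum; all-zero unchanged)."""
    if mode == "none":
        return image
    if mode == "TIC":
        if per_pixel_tic is None:
            raise ValueError("TIC normalization requires a per-pixel TIC array")
        if per_pixel_tic.shape != image.values.shape:
            raise ValueError("TIC array shape mismatch")
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(per_pixel_tic > 0, image.values / per_pixel_tic, 0.0)
    elif mode == "max":
        m = image.values.max()
        v = image.values / m if m > 0 else image.values.copy()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return IonImage(values=v, target=image.target,
                    channels_used=image.channels_used, normalization=mode)


def compose(images: Mapping[str, IonImage]) -> CompositeImage:
    """Overlay ion images as color channels (e.g. vessel red, complex blue)."""
    return CompositeImage(channel_images=dict(images))


def region_statistics(
    image: IonImage,
    mask: np.ndarray,
    labels: Mapping[int, str] | None = None,
    detection_threshold: float = 0.0,
) -> dict[str, dict[str, float]]:
    """Per-region mean / median / fraction-nonzero of an ion image.

    ``mask`` holds integer region labels; ``labels`` maps them to names
    (defaults to the phantom's background/bulk_tissue/vessel scheme). Labels
    present in the mask but not in ``labels`` raise. ``fraction_nonzero``
    counts pixels above ``detection_threshold`` (default: strictly positive),
    so a noise-level threshold turns it into a detection fraction.
    """
    if mask.shape != image.values.shape:
        raise ValueError("mask shape mismatch")
    labels = dict(REGION_NAMES) if labels is None else dict(labels)
    out: dict[str, dict[str, float]] = {}
    for lab in np.unique(mask):
        if int(lab) not in labels:
            raise ValueError(f"unknown region label {int(lab)}")
        sel = image.values[mask == lab]
        out[labels[int(lab)]] = {
            "mean": float(sel.mean()),
            "median": float(np.median(sel)),
            "fraction_nonzero": float((sel > detection_threshold).mean()),
            "n_pixels": float(sel.size),
        }
    return out


def confirm_targets(
    dataset: LineScanDataset,
    entries,
    model=None,
    min_products: int = 2,
):
    """MRM-like confirmation of each target against the whole dataset.

    Averages all pixel spectra (noise shrinks as 1/sqrt(n_pixels)), centroids
    the consensus at a correspondingly reduced noise floor, and matches each
    entry's predicted product ladder against it. Returns one
    :class:`~tptcr.targeting.MatchReport` per entry.
    """
    from dataclasses import replace as _replace

    from .simulate import SpectralModel, _centroid
    from .targeting import match_products

    model = model or SpectralModel()
    n = len(dataset.spectra)
    mz = dataset.spectra[0].mz
    total = np.zeros_like(mz)
    for spec in dataset.spectra:
        total += spec.intensity
    consensus_model = _replace(model, noise_floor=model.noise_floor / np.sqrt(n))
    cen = _centroid(mz, total / n, consensus_model, {})
    return [match_products(cen.mz, cen.intensity, e, min_products=min_products)
            for e in entries]
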