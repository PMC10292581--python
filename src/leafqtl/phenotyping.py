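"""Plant segmentation, cover area, median spectra and vegetation indices.

The segmentation rule exploits the red-edge contrast of living vegetation:
a pixel is plant iff its near-infrared (800 nm) reflectance strictly exceeds
its red (680 nm) reflectance.  Pots, soil and other background lack this
contrast.  Per-band medians over the plant mask summarise the spectrum of
one plant, and dividing by their sum removes the global illumination scale
(weather varies between measurement days); the resulting nine proportions
are the phenotype unit everything downstream consumes.

Fifteen vegetation indices are computed from the standardized proportions.
Ratio-form indices are unchanged by the standardization; CARI, MCARI, CRI1,
CRI2 and ARI are not ratio-form, so their absolute values depend on it, but
between-plant rankings under a shared illumination factor are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .band_io import SpectralImage

__all__ = [
    "INDEX_NAMES",
    "PlantMask",
    "RawSpectrum",
    "StandardizedSpectrum",
    "segment_plant",
    "cover_area",
    "median_spectrum",
    "standardize_spectrum",
    "compute_vegetation_indices",
]

#: The fifteen vegetation indices, in reporting order.
INDEX_NAMES = (
    "NDVI", "SR", "EVI", "VARI", "ViGreen", "SIPI", "PSND", "CARI",
    "MCARI", "ARI", "RGRI", "ACI", "CRI1", "CRI2", "PRI",
)


@dataclass
class PlantMask:
    """Boolean plant/background raster for one image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_plant_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RawSpectrum:
    """Per-band median reflectances over the plant mask, each in [0, 1]."""

    plant_id: str
    date: str
    r: dict[int, float] = field(default_factory=dict)  # wavelength nm -> median


@dataclass
class StandardizedSpectrum:
    """Nine band proportions summing to one — the leaf-colour phenotype."""

    plant_id: str
    date: str
    p: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.array(list(self.p.values()), dtype=float)
        if vals.size and (abs(vals.sum() - 1.0) > 1e-9 or (vals < 0).any()):
            raise ValueError("proportions must be nonnegative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p[nm] for nm in sorted(self.p)], dtype=float)


def segment_plant(img: SpectralImage, nir_nm: int = 800, red_nm: int = 680,
                  min_object_size: int = 0) -> PlantMask:
    """Classify pixels as plant where NIR reflectance strictly exceeds red.

    Ties count as background.  ``min_object_size`` optionally removes small
    connected components (off by default; no morphological cleanup is applied
    unless requested).
    """
    nir = img.band(nir_nm)
    red = img.band(red_nm)
    mask = nir > red
    if min_object_size > 0:
        from skimage.morphology import remove_small_objects
        mask = remove_small_objects(mask, min_size=min_object_size)
    return PlantMask(mask=mask)


def cover_area(mask: PlantMask, pixel_area: float | None = None) -> float:
    """Vegetation-covered area: plant pixel count, or physical area if
    ``pixel_area`` (area per pixel) is given."""
    n = mask.n_plant_pixels
    return n * pixel_area if pixel_area is not None else float(n)


def median_spectrum(img: SpectralImage, mask: PlantMask) -> RawSpectrum:
    """Per-band median over masked pixels (even counts: mean of middle two)."""
    if mask.mask.shape != img.shape:
        raise ValueError("mask dimensions do not match image")
    if mask.n_plant_pixels < 1:
        raise ValueError("no plant pixels: plant absent or image invalid")
    med = np.median(img.pixels[mask.mask], axis=0)
    r = {nm: float(v) for nm, v in zip(img.bands.wavelengths_nm, med)}
    return RawSpectrum(plant_id=img.plant_id, date=img.capture_date, r=r)


def standardize_spectrum(raw: RawSpectrum) -> StandardizedSpectrum:
    """Rescale the band medians so they sum to one.

    Removes the multiplicative illumination factor shared by all bands of one
    capture.  An all-zero spectrum carries no colour information and is
    rejected.
    """
    vals = np.array([raw.r[nm] for nm in sorted(raw.r)], dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: band medians sum to zero")
    p = {nm: raw.r[nm] / total for nm in sorted(raw.r)}
    return StandardizedSpectrum(plant_id=raw.plant_id, date=raw.date, p=p)


def _safe(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: division by zero, index undefined", RuntimeWarning)
        return float("nan")
    return num / den


def compute_vegetation_indices(s: StandardizedSpectrum) -> dict[str, float]:
    """Evaluate the fifteen vegetation indices on a standardized spectrum.

    Band proportions are referred to by wavelength.  Grouped by what each
    index tracks: biomass (NDVI, SR, EVI, VARI, ViGreen), pigments
    (SIPI, PSND), chlorophyll (CARI, MCARI), anthocyanins (ARI, RGRI, ACI),
    carotenoids (CRI1, CRI2) and light-use efficiency (PRI).

    A division by zero makes that one index NaN with a warning; the others
    are still computed, so a single degenerate plant cannot abort a
    population run.
    """
    p = s.p
    b445, b500, b532 = p[445], p[500], p[532]
    b550, b568, b676 = p[550], p[568], p[676]
    b680, b700, b800 = p[680], p[700], p[800]

    cari = b700 - b676 - 0.2 * (b700 - b550)
    out = {
        "NDVI": _safe(b800 - b676, b800 + b676, "NDVI"),
        "SR": _safe(b800, b676, "SR"),
        "EVI": _safe(2.5 * (b800 - b676), b800 + 6 * b676 - 7.5 * b500 + 1, "EVI"),
        "VARI": _safe(b550 - b676, b550 + b676 - b500, "VARI"),
        "ViGreen": _safe(b550 - b676, b550 + b676, "ViGreen"),
        "SIPI": _safe(b800 - b445, b800 - b680, "SIPI"),
        "PSND": _safe(b800 - b445, b800 + b445, "PSND"),
        "CARI": cari,
        "MCARI": cari * _safe(b700, b676, "MCARI"),
        "ARI": _safe(1.0, b550, "ARI") - _safe(1.0, b700, "ARI"),
        "RGRI": _safe(b676, b550, "RGRI"),
        "ACI": _safe(b550, b800, "ACI"),
        "CRI1": _safe(1.0, b500, "CRI1") - _safe(1.0, b550, "CRI1"),
        "CRI2": _safe(1.0, b500, "CRI2") - _safe(1.0, b700, "CRI2"),
        "PRI": _safe(b532 - b568, b532 + b568, "PRI"),
    }
    return out
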