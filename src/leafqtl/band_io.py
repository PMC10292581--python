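"""Reading, validation and writing of multispectral stacks and tabular artifacts.

The imaging system captures one grayscale plane per narrow spectral band.  This
module assembles such planes (single files per band, or one multi-page TIFF)
into a :class:`SpectralImage` with intensities rescaled to [0, 1], and provides
CSV readers/writers for the tables the pipeline exchanges: standardized
spectra, vegetation indices, marker genotypes, genetic maps and scan results.

Co-registration of the band planes is assumed (a static pot imaged from a
fixed mount); no alignment is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "BandSet",
    "SpectralImage",
    "MarkerGenotypes",
    "load_band_images",
    "write_table",
    "read_table",
    "read_genotypes",
    "write_genotypes",
]

#: Centre wavelengths (nm) of the nine camera bands, ascending.
DEFAULT_WAVELENGTHS = (445, 500, 532, 550, 568, 676, 680, 700, 800)


@dataclass(frozen=True)
class BandSet:
    """The set of spectral bands an image stack is expected to carry.

    Parameters
    ----------
    wavelengths_nm
        Centre wavelengths in nanometres, strictly increasing, no duplicates.
    bandwidth_nm
        Full width of each band filter in nanometres (one value per band).
    """

    wavelengths_nm: tuple[int, ...] = DEFAULT_WAVELENGTHS
    bandwidth_nm: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        wl = tuple(int(w) for w in self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", wl)
        if len(set(wl)) != len(wl):
            raise ValueError("duplicate wavelengths in band set")
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("wavelengths must be strictly increasing")
        bw = self.bandwidth_nm
        if bw is None:
            bw = (10,) * len(wl)
        else:
            bw = tuple(int(b) for b in bw)
            if len(bw) != len(wl):
                raise ValueError("one bandwidth per wavelength required")
        object.__setattr__(self, "bandwidth_nm", bw)

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def index(self, nm: int) -> int:
        """Position of band ``nm`` in the stack; raises if absent."""
        try:
            return self.wavelengths_nm.index(nm)
        except ValueError:
            raise KeyError(f"band {nm} nm not in band set") from None


@dataclass
class SpectralImage:
    """A co-registered multi-band reflectance raster for one plant.

    ``pixels`` is an H×W×B float array in [0, 1]; band order always follows
    ascending wavelength of ``bands``.
    """

    bands: BandSet
    pixels: np.ndarray
    plant_id: str = ""
    capture_date: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != len(self.bands):
            raise ValueError(
                f"pixels must be H×W×{len(self.bands)}, got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("non-finite pixel values")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values outside [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, nm: int) -> np.ndarray:
        """The H×W plane for wavelength ``nm``."""
        return self.pixels[:, :, self.bands.index(nm)]


_WAVELENGTH_RE = re.compile(r"(\d{3})")


def _infer_wavelength(path: Path, bands: BandSet) -> int:
    """Pick the band wavelength embedded in a file name (e.g. ``plant_800.tif``)."""
    hits = [int(m) for m in _WAVELENGTH_RE.findall(path.stem)]
    hits = [h for h in hits if h in bands.wavelengths_nm]
    if len(set(hits)) != 1:
        raise ValueError(f"cannot infer band wavelength from file name {path.name!r}")
    return hits[0]


def _rescale(plane: np.ndarray, path: Path) -> np.ndarray:
    if plane.ndim == 3:  # RGB-decoded grayscale: collapse identical channels
        plane = plane[..., 0]
    if plane.dtype == np.uint8:
        return plane.astype(float) / 255.0
    if plane.dtype == np.uint16:
        return plane.astype(float) / 65535.0
    if np.issubdtype(plane.dtype, np.floating):
        if plane.min() < 0 or plane.max() > 1:
            raise ValueError(f"float image {path.name} outside [0, 1]")
        return plane.astype(float)
    raise ValueError(f"unsupported bit depth {plane.dtype} in {path.name}")


def load_band_images(
    paths: Sequence[str | Path] | Mapping[int, str | Path] | str | Path,
    bands: BandSet | None = None,
    plant_id: str = "",
    capture_date: str = "",
) -> SpectralImage:
    """Assemble one :class:`SpectralImage` from per-band files or a multi-page TIFF.

    Parameters
    ----------
    paths
        Either a mapping ``{wavelength_nm: path}``, a sequence of per-band file
        paths (wavelengths inferred from the file names), or a single
        multi-page TIFF whose page order is ascending wavelength.
    bands
        Expected band set; defaults to the nine-band camera layout.

    Raises
    ------
    FileNotFoundError
        If a listed file does not exist.
    ValueError
        On a missing band ("missing band λ"), mismatched plane dimensions
        ("unregistered stack"), or unsupported bit depth.
    """
    import imageio.v3 as iio

    bands = bands or BandSet()
    planes: dict[int, np.ndarray] = {}

    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if not p.exists():
            raise FileNotFoundError(p)
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(bands):
            missing = bands.wavelengths_nm[min(stack.shape[0], len(bands) - 1)]
            raise ValueError(f"missing band {missing}: stack has {stack.shape[0]} pages")
        for nm, plane in zip(bands.wavelengths_nm, stack):
            planes[nm] = _rescale(plane, p)
    else:
        if isinstance(paths, Mapping):
            items: Iterable[tuple[int, Path]] = ((int(k), Path(v)) for k, v in paths.items())
        else:
            items = ((None, Path(p)) for p in paths)  # type: ignore[misc]
        for nm, p in items:
            if not p.exists():
                raise FileNotFoundError(p)
            if nm is None:
                nm = _infer_wavelength(p, bands)
            if nm not in bands.wavelengths_nm:
                raise ValueError(f"unexpected band {nm} nm")
            if nm in planes:
                raise ValueError(f"duplicate band {nm} nm")
            planes[nm] = _rescale(np.asarray(iio.imread(p)), p)

    for nm in bands.wavelengths_nm:
        if nm not in planes:
            raise ValueError(f"missing band {nm}")
    shapes = {pl.shape for pl in planes.values()}
    if len(shapes) != 1:
        raise ValueError(f"unregistered stack: plane shapes {sorted(shapes)}")

    pixels = np.stack([planes[nm] for nm in bands.wavelengths_nm], axis=-1)
    return SpectralImage(bands=bands, pixels=pixels, plant_id=plant_id,
                         capture_date=capture_date)


# ---------------------------------------------------------------------------
# tabular artifacts


def write_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> Path:
    """Write a tabular artifact as UTF-8 CSV with a header row.

    Round-trips losslessly through :func:`read_table`.  Empty inputs are
    rejected: an empty artifact is always a pipeline error upstream.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


VALID_GENOTYPE_CODES = frozenset({"A", "H", "-"})


@dataclass
class MarkerGenotypes:
    """Genotypes of the two parents and the F1 block at genome-wide markers.

    Codes: ``A`` homozygous, ``H`` heterozygous, ``-`` missing.  Rows are
    individuals; the two parents are stored apart from the F1 progeny.
    """

    parent_genotypes: pd.DataFrame  # index: [P1, P2]
    f1_genotypes: pd.DataFrame      # index: F1 individual ids

    def __post_init__(self) -> None:
        for df in (self.parent_genotypes, self.f1_genotypes):
            bad = set(np.unique(df.to_numpy())) - VALID_GENOTYPE_CODES
            if bad:
                raise ValueError(f"invalid genotype codes {sorted(bad)}")
        if list(self.parent_genotypes.columns) != list(self.f1_genotypes.columns):
            raise ValueError("parent and F1 marker columns differ")
        if self.f1_genotypes.columns.duplicated().any():
            raise ValueError("duplicate marker names")

    @property
    def marker_names(self) -> list[str]:
        return list(self.f1_genotypes.columns)

    @property
    def n_f1(self) -> int:
        return len(self.f1_genotypes)

    @property
    def n_markers(self) -> int:
        return self.f1_genotypes.shape[1]

    @property
    def all_missing_markers(self) -> list[str]:
        """Markers with no called F1 genotype at all (retained but flagged)."""
        g = self.f1_genotypes.to_numpy()
        flag = (g == "-").all(axis=0)
        return [m for m, f in zip(self.marker_names, flag) if f]


def read_genotypes(path: str | Path) -> MarkerGenotypes:
    """Read a marker genotype CSV: one row per individual, one column per marker.

    The first column holds individual ids; the first two data rows are the
    parents P1 and P2, the rest the F1 population.  Cells must be in
    ``{A, H, -}``.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] < 3:
        raise ValueError("genotype table needs 2 parent rows plus F1 rows")
    if df.columns.duplicated().any():
        raise ValueError("duplicate marker names")
    bad = set(np.unique(df.to_numpy())) - VALID_GENOTYPE_CODES
    if bad:
        raise ValueError(f"parse error: invalid genotype codes {sorted(bad)}")
    return MarkerGenotypes(parent_genotypes=df.iloc[:2], f1_genotypes=df.iloc[2:])


def write_genotypes(g: MarkerGenotypes, path: str | Path) -> Path:
    df = pd.concat([g.parent_genotypes, g.f1_genotypes])
    df.index.name = "id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)
    return path
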