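"""Synthetic multispectral scenes and simulated pseudo-testcross populations.

Every other module's statistical assumptions are generated here with known
ground truth: scenes carry an exact plant mask, crosses carry their true map
and planted QTL effects.  All generators are pure functions of their seed
and parameters.

Scenes place a plant region (disk or blob) drawn from a foreground spectral
profile over a background profile.  Foreground profiles keep the living-
vegetation red edge (800 nm mean above 680 nm), background does not, so the
NIR>red segmentation rule recovers the ground-truth mask exactly when noise
is off.  The "green_leaf" profile peaks in the green bands; "dormant_leaf"
shifts reflectance toward 676–700 nm and depresses green, the reflectance
shape of anthocyanic over-wintering foliage.

Crosses follow the pseudo-testcross design: each parent contributes its own
linkage groups on which markers segregate 1:1 via a two-state Markov chain
with recombination from the chosen map function.  Planted QTLs act through
the genotype at their nearest marker, either directly on a quantitative
trait or on the rendered leaf spectrum of each individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .band_io import BandSet, MarkerGenotypes, SpectralImage
from .linkage_map import distance_to_rf

__all__ = [
    "SpectralProfile",
    "SyntheticScene",
    "QTL",
    "SimulatedCross",
    "default_profiles",
    "generate_scene",
    "simulate_pseudo_testcross",
    "plant_qtl_effects",
    "render_population_images",
]


@dataclass(frozen=True)
class SpectralProfile:
    """Per-band mean reflectances and noise level for one scene material."""

    means: tuple[float, ...]
    noise_sd: float
    label: str  # green_leaf | dormant_leaf | background

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.means)
        object.__setattr__(self, "means", m)
        if len(m) != 9:
            raise ValueError("profile needs 9 band means")
        if min(m) < 0 or max(m) > 1:
            raise ValueError("profile means must lie in [0, 1]")
        # bands ascending: index 6 = 680 nm, index 8 = 800 nm
        if self.label in ("green_leaf", "dormant_leaf") and not m[8] > m[6]:
            raise ValueError(f"{self.label} must have 800 nm mean > 680 nm mean")
        if self.label == "background" and m[8] > m[6]:
            raise ValueError("background must have 800 nm mean <= 680 nm mean")

    def mix(self, other: "SpectralProfile", w: float,
            label: str | None = None) -> "SpectralProfile":
        """Convex mixture: w of self, (1−w) of ``other``."""
        m = tuple(w * a + (1 - w) * b for a, b in zip(self.means, other.means))
        return SpectralProfile(means=m, noise_sd=self.noise_sd,
                               label=label or self.label)


def default_profiles() -> dict[str, SpectralProfile]:
    """The packaged default green-leaf / dormant-leaf / background profiles."""
    text = resources.files("leafqtl").joinpath("_profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    return {k: SpectralProfile(means=tuple(v["means"]), noise_sd=v["noise_sd"],
                               label=k) for k, v in raw.items()}


@dataclass
class SyntheticScene:
    image: SpectralImage
    truth_mask: np.ndarray
    foreground: SpectralProfile
    background: SpectralProfile
    seed: int


def _disk_mask(shape: tuple[int, int], radius: float,
               center: tuple[float, float] | None = None) -> np.ndarray:
    """Disk rasterised with pixel centres at integer coordinates and strict
    inclusion (x² + y² < r²); default centre is the image centre (H−1)/2."""
    h, w = shape
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius**2


def _blob_mask(shape: tuple[int, int], radius: float, n_lobes: int,
               rng: np.random.Generator) -> np.ndarray:
    """Irregular plant silhouette: union of lobes around the centre."""
    h, w = shape
    mask = _disk_mask(shape, radius)
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0.4, 0.9) * radius
        r = rng.uniform(0.3, 0.6) * radius
        cy = (h - 1) / 2.0 + d * np.sin(ang)
        cx = (w - 1) / 2.0 + d * np.cos(ang)
        mask |= _disk_mask(shape, r, center=(cy, cx))
    return mask


def generate_scene(shape: tuple[int, int] = (64, 64),
                   geometry: str = "disk", radius: float = 16.0,
                   n_lobes: int = 4,
                   profile: SpectralProfile | None = None,
                   background_profile: SpectralProfile | None = None,
                   noise_sd: float | None = None,
                   seed: int = 0,
                   plant_id: str = "", capture_date: str = "") -> SyntheticScene:
    """One multispectral scene with a known plant mask.

    ``noise_sd`` overrides both profiles' noise; 0 makes the scene exactly
    the profile means, so the rule-based segmentation equals the truth mask.
    Pixels are clipped to [0, 1] after noise.
    """
    profs = default_profiles()
    fg = profile or profs["green_leaf"]
    bg = background_profile or profs["background"]
    rng = np.random.default_rng(seed)
    h, w = shape
    if geometry == "disk":
        if radius > min(h, w) / 2.0:
            raise ValueError("disk does not fit in shape")
        mask = _disk_mask(shape, radius)
    elif geometry == "blob":
        mask = _blob_mask(shape, radius, n_lobes, rng)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    fg_sd = fg.noise_sd if noise_sd is None else noise_sd
    bg_sd = bg.noise_sd if noise_sd is None else noise_sd
    px = np.empty((h, w, 9))
    px[:] = np.asarray(bg.means)
    px[mask] = np.asarray(fg.means)
    if fg_sd > 0 or bg_sd > 0:
        noise = rng.normal(0.0, 1.0, size=px.shape)
        sd = np.where(mask[..., None], fg_sd, bg_sd)
        px = px + sd * noise
    px = np.clip(px, 0.0, 1.0)
    img = SpectralImage(bands=BandSet(), pixels=px, plant_id=plant_id,
                        capture_date=capture_date)
    return SyntheticScene(image=img, truth_mask=mask, foreground=fg,
                          background=bg, seed=seed)


@dataclass(frozen=True)
class QTL:
    """A planted quantitative trait locus on the simulated map."""

    parent: str        # "P1" | "P2"
    group: int         # 0-based group index within that parent's map
    position_cM: float
    effect: float = 1.0  # additive shift carried by the H class, trait-SD units


@dataclass
class SimulatedCross:
    """An F1 pseudo-testcross population with known map and genotypes.

    ``true_states`` holds the unmasked chain states (N × M, 0/1) so planted
    QTL effects are computed from truth even when the released genotype
    table has missing cells.
    """

    genotypes: MarkerGenotypes
    true_states: np.ndarray
    marker_meta: pd.DataFrame   # marker, parent, group, position_cM
    map_function: str
    seed: int
    qtls: list[QTL] = field(default_factory=list)

    def marker_index(self, name: str) -> int:
        return self.genotypes.marker_names.index(name)

    def nearest_marker(self, q: QTL) -> str:
        sub = self.marker_meta[(self.marker_meta["parent"] == q.parent)
                               & (self.marker_meta["group"] == q.group)]
        if sub.empty:
            raise ValueError(f"QTL group {q.parent}/{q.group} not simulated")
        j = (sub["position_cM"] - q.position_cM).abs().idxmin()
        return str(sub.loc[j, "marker"])

    def qtl_states(self, q: QTL) -> np.ndarray:
        """True 0/1 state of every F1 at the marker nearest the QTL."""
        return self.true_states[:, self.marker_index(self.nearest_marker(q))]

    def true_group_markers(self, q: QTL) -> list[str]:
        """All simulated markers on the QTL's true chromosome."""
        sub = self.marker_meta[(self.marker_meta["parent"] == q.parent)
                               & (self.marker_meta["group"] == q.group)]
        return list(sub["marker"])


def simulate_pseudo_testcross(n_f1: int = 94, groups_per_parent: int = 3,
                              markers_per_group: int = 8,
                              spacing_cM: float = 10.0,
                              map_function: str = "haldane",
                              missing_rate: float = 0.0,
                              seed: int = 0) -> SimulatedCross:
    """Simulate an F1 pseudo-testcross population.

    For each parental linkage group and individual, a two-state Markov chain
    runs along equally spaced markers, flipping between adjacent markers with
    probability given by the inverse map function of the spacing.  Markers on
    the P1 map are heterozygous in P1 and homozygous in P2 (and vice versa),
    so each map's markers segregate 1:1 through one parent's meioses only.
    ``missing_rate`` masks F1 genotype calls at random in the released table.
    """
    if spacing_cM <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    r = distance_to_rf(spacing_cM, map_function)

    names, parents, groups, positions = [], [], [], []
    states_cols = []
    for parent in ("P1", "P2"):
        for gi in range(groups_per_parent):
            prev = rng.integers(0, 2, size=n_f1)
            for mi in range(markers_per_group):
                if mi > 0:
                    flip = rng.random(n_f1) < r
                    prev = np.where(flip, 1 - prev, prev)
                names.append(f"{parent}g{gi + 1}m{mi + 1:02d}")
                parents.append(parent)
                groups.append(gi)
                positions.append(mi * spacing_cM)
                states_cols.append(prev.copy())
    states = np.column_stack(states_cols)

    sym = np.where(states == 1, "H", "A")
    if missing_rate > 0:
        miss = rng.random(sym.shape) < missing_rate
        sym = np.where(miss, "-", sym)

    f1_ids = [f"F1_{i + 1:03d}" for i in range(n_f1)]
    f1 = pd.DataFrame(sym, index=f1_ids, columns=names)
    p1_row = ["H" if p == "P1" else "A" for p in parents]
    p2_row = ["H" if p == "P2" else "A" for p in parents]
    par = pd.DataFrame([p1_row, p2_row], index=["P1", "P2"], columns=names)
    meta = pd.DataFrame({"marker": names, "parent": parents, "group": groups,
                         "position_cM": positions})
    return SimulatedCross(
        genotypes=MarkerGenotypes(parent_genotypes=par, f1_genotypes=f1),
        true_states=states, marker_meta=meta, map_function=map_function,
        seed=seed)


def plant_qtl_effects(cross: SimulatedCross, qtls: list[QTL],
                      h2: float | None = None, noise_sd: float | None = None,
                      seed: int = 0) -> np.ndarray:
    """A quantitative trait with additive planted QTL effects.

    y_i = Σ_q effect_q · 1[state at q's nearest marker = 1] + ε_i.  Noise is
    Gaussian, either with explicit ``noise_sd`` or scaled so the realised
    genetic variance makes up heritability ``h2`` of the total.
    """
    if (h2 is None) == (noise_sd is None):
        raise ValueError("give exactly one of h2 or noise_sd")
    if h2 is not None and not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    y_gen = np.zeros(cross.genotypes.n_f1)
    for q in qtls:
        y_gen = y_gen + q.effect * cross.qtl_states(q)
    if noise_sd is None:
        var_g = float(np.var(y_gen))
        if var_g == 0 and h2 < 1:
            raise ValueError("no genetic variance: cannot target h2 < 1")
        noise_sd = float(np.sqrt(var_g * (1 - h2) / h2)) if h2 < 1 else 0.0
    cross.qtls = list(qtls)
    return y_gen + rng.normal(0.0, noise_sd, size=len(y_gen))


def render_population_images(
    cross: SimulatedCross,
    colour_qtl: QTL,
    nir_qtl: QTL | None = None,
    colour_weight: dict[int, float] | None = None,
    weight_sd: float = 0.2,
    nir_boost: dict[int, float] | None = None,
    nir_boost_sd: float = 0.035,
    radius_range: tuple[float, float] = (10.0, 16.0),
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.01,
    seed: int = 0,
    capture_date: str = "",
) -> dict[str, SyntheticScene]:
    """Render one scene per F1 whose leaf spectrum depends on planted QTLs.

    The colour QTL sets each individual's green-versus-dormant mixture
    weight: genotype class → mean weight via ``colour_weight`` (default
    {0: 0.75, 1: 0.30}: the heterozygous class is red-shifted), plus
    individual Gaussian variation ``weight_sd`` (clipped to [0, 1]) standing
    in for the many unmodelled causes of plant-to-plant variation.  Plant
    radius grows linearly with the green weight across ``radius_range``, so
    cover area and the red-shift are negatively associated, as in spring
    dormancy-break phenotypes.

    The optional NIR QTL adds ``nir_boost`` (default {0: 0.0, 1: 0.18} plus
    ``nir_boost_sd`` individual noise) to the 800-nm mean, moving the
    NIR-based biomass indices without touching the visible bands.

    Registers both QTLs on ``cross.qtls``; returns {plant_id: scene}.
    """
    profs = default_profiles()
    green, dormant, bg = (profs["green_leaf"], profs["dormant_leaf"],
                          profs["background"])
    colour_weight = colour_weight if colour_weight is not None else {0: 0.75, 1: 0.30}
    nir_boost = nir_boost if nir_boost is not None else {0: 0.0, 1: 0.18}
    rng = np.random.default_rng(seed)

    c_states = cross.qtl_states(colour_qtl)
    n_states = cross.qtl_states(nir_qtl) if nir_qtl is not None else None
    cross.qtls = [colour_qtl] + ([nir_qtl] if nir_qtl is not None else [])

    scenes: dict[str, SyntheticScene] = {}
    ids = list(cross.genotypes.f1_genotypes.index.astype(str))
    for i, pid in enumerate(ids):
        w = float(np.clip(colour_weight[int(c_states[i])]
                          + rng.normal(0.0, weight_sd), 0.0, 1.0))
        fg = green.mix(dormant, w, label="green_leaf")
        if n_states is not None:
            boost = float(np.clip(nir_boost[int(n_states[i])]
                                  + rng.normal(0.0, nir_boost_sd), 0.0, 0.35))
            means = list(fg.means)
            means[8] = min(means[8] + boost, 1.0)
            fg = SpectralProfile(means=tuple(means), noise_sd=fg.noise_sd,
                                 label="green_leaf")
        radius = radius_range[0] + w * (radius_range[1] - radius_range[0])
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scenes[pid] = generate_scene(
            shape=shape, geometry="disk", radius=radius, profile=fg,
            background_profile=bg, noise_sd=noise_sd, seed=scene_seed,
            plant_id=pid, capture_date=capture_date)
    return scenes


def write_scene(scene: SyntheticScene, directory: str | Path) -> Path:
    """Write a scene as multi-page TIFF plus a 0/255 mask PNG."""
    import imageio.v3 as iio
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = scene.image.plant_id or "scene"
    stack = np.moveaxis((scene.image.pixels * 65535).round().astype(np.uint16),
                        -1, 0)
    path = directory / f"{pid}.tif"
    tifffile.imwrite(path, stack)
    iio.imwrite(directory / f"{pid}_mask.png",
                (scene.truth_mask * 255).astype(np.uint8))
    return path
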