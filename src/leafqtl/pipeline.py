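"""End-to-end orchestration: images → phenotypes → multivariate traits → QTLs.

One configured run turns a set of multispectral captures and a genotype
table into the full 27-trait phenotype table (cover area, nine standardized
bands, PC1/PC2, fifteen vegetation indices), a parent-specific genetic map,
per-trait LOD scans with permutation thresholds, a QTL table, and — when at
least two significant QTLs exist — the four-class genotype comparison with
one-way ANOVA.  Failures isolate at plant/trait granularity and are always
logged; a run is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import band_io, linkage_map, multivariate, phenotyping, qtl_scan
from .band_io import MarkerGenotypes, SpectralImage
from .synthetic_data import SyntheticScene

logger = logging.getLogger("leafqtl")

__all__ = ["RunConfig", "TRAIT_COLUMNS", "run_phenotyping", "run_qtl", "run"]

#: The 27 trait columns, in reporting order.
TRAIT_COLUMNS = (
    ("area",)
    + tuple(str(nm) for nm in band_io.DEFAULT_WAVELENGTHS)
    + ("PC1", "PC2")
    + phenotyping.INDEX_NAMES
)


@dataclass
class RunConfig:
    """Settings for one pipeline run; defaults follow the study protocol:
    2 cM probability grid, 1,000 permutations, 5%/10% levels, 30 cM CIM
    window, Haldane map function."""

    image_dir: str | None = None
    genotypes_csv: str | None = None
    out_dir: str = "leafqtl_out"
    map_function: str = "haldane"
    step_cM: float = 2.0
    window_cM: float = 30.0
    n_cofactors: int = 3
    n_permutations: int = 1000
    alphas: tuple[float, float] = (0.05, 0.10)
    seed: int = 0
    traits: tuple[str, ...] | None = None  # None → all 27


def run_phenotyping(
    images: dict[str, SpectralImage] | dict[str, SyntheticScene] | str | Path,
    date: str = "",
) -> pd.DataFrame:
    """Phenotype a set of captures into the 27-trait table.

    ``images`` maps plant id → SpectralImage (or SyntheticScene), or names a
    directory of multi-page TIFFs (one per plant, pages in ascending
    wavelength).  Plants whose mask is empty are skipped with a log entry.
    PCA (covariance, per run) of the nine standardized bands supplies PC1
    and PC2.
    """
    if isinstance(images, (str, Path)):
        paths = sorted(Path(images).glob("*.tif*"))
        images = {p.stem: band_io.load_band_images(p, plant_id=p.stem)
                  for p in paths if not p.stem.endswith("_mask")}
    rows: dict[str, dict] = {}
    for pid, item in images.items():
        img = item.image if isinstance(item, SyntheticScene) else item
        try:
            mask = phenotyping.segment_plant(img)
            area = phenotyping.cover_area(mask)
            raw = phenotyping.median_spectrum(img, mask)
            std = phenotyping.standardize_spectrum(raw)
        except ValueError as e:
            logger.warning("plant %s skipped: %s", pid, e)
            continue
        row = {"area": area}
        row.update({str(nm): v for nm, v in std.p.items()})
        row.update(phenotyping.compute_vegetation_indices(std))
        rows[pid] = row
        logger.info("plant %s phenotyped (area=%d)", pid, int(area))
    if not rows:
        raise RuntimeError("zero successfully phenotyped plants")
    table = pd.DataFrame.from_dict(rows, orient="index")
    band_cols = [str(nm) for nm in band_io.DEFAULT_WAVELENGTHS]
    pca = multivariate.run_pca(table[band_cols])
    table["PC1"] = pca.scores[:, 0]
    table["PC2"] = pca.scores[:, 1]
    table = table[list(TRAIT_COLUMNS)]
    table.index.name = "plant_id"
    if date:
        table["date"] = date
        table = table[["date", *TRAIT_COLUMNS]]
    return table


def run_qtl(config: RunConfig, phenotypes: pd.DataFrame,
            genotypes: MarkerGenotypes) -> dict:
    """Scan every trait, threshold by permutation, and compare QTL classes.

    Returns a dict with the genetic map, per-trait scans and thresholds, the
    QTL table, a trait × group peak-LOD matrix, and (when two significant
    QTLs on distinct groups exist) the genotype-class ANOVA for the two
    top-LOD traits.
    """
    gmap = linkage_map.build_maps(genotypes, map_function=config.map_function)
    probs = qtl_scan.genotype_probabilities(gmap, genotypes,
                                            step_cM=config.step_cM)
    ids = probs.individuals
    traits = list(config.traits or [c for c in phenotypes.columns
                                    if c in TRAIT_COLUMNS])
    pheno = phenotypes.reindex(ids)

    scans: dict[str, qtl_scan.ScanResult] = {}
    thresholds: dict[str, qtl_scan.PermutationThresholds] = {}
    qtl_rows = []
    rng = np.random.default_rng(config.seed)
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        if np.isfinite(y).sum() < 20:
            logger.warning("trait %s skipped: too few phenotyped individuals",
                           trait)
            continue
        scan = qtl_scan.cim_scan(probs, y, window_cM=config.window_cM,
                                 n_cofactors=config.n_cofactors, trait=trait)
        thr = qtl_scan.permutation_thresholds(
            probs, y, n=config.n_permutations, alphas=config.alphas,
            seed=int(rng.integers(0, 2**31 - 1)), method="cim",
            window_cM=config.window_cM, n_cofactors=config.n_cofactors)
        scan.threshold_5, scan.threshold_10 = thr.threshold_5, thr.threshold_10
        scans[trait] = scan
        thresholds[trait] = thr
        qtls = qtl_scan.significant_qtls(scan, thr)
        qtl_rows.append(qtls)
        logger.info("trait %s scanned: max LOD %.2f, %d QTL(s)", trait,
                    scan.max_lod, len(qtls))
    qtl_table = (pd.concat(qtl_rows, ignore_index=True) if qtl_rows
                 else pd.DataFrame(columns=["trait", "group", "position_cM",
                                            "lod", "level"]))

    # trait × group matrix of peak LODs (machine analogue of a QTL heat map)
    peak = pd.DataFrame({
        t: s.table.groupby("group")["lod"].max() for t, s in scans.items()
    }).T

    anova = None
    sig5 = qtl_table[qtl_table["level"] == "5%"]
    if len(sig5) >= 2 and sig5["group"].nunique() >= 2:
        top = (sig5.sort_values("lod", ascending=False)
               .drop_duplicates("group").head(2))
        markers, top_traits = [], []
        for _, row in top.iterrows():
            gp = probs.groups[row["group"]]
            j = int(np.argmin(np.abs(gp.marker_positions - row["position_cM"])))
            markers.append(gp.marker_names[j])
            top_traits.append(row["trait"])
        classes = qtl_scan.classify_by_qtl_markers(genotypes, markers[0],
                                                   markers[1])
        anova = {}
        for trait in dict.fromkeys(top_traits):
            anova[trait] = qtl_scan.compare_groups_anova(
                classes, pheno[trait], alpha=0.01)
        anova["markers"] = markers
        anova["class_counts"] = classes.value_counts().to_dict()

    return {"map": gmap, "probs": probs, "scans": scans,
            "thresholds": thresholds, "qtl_table": qtl_table,
            "peak_lod_matrix": peak, "anova": anova}


def run(config: RunConfig,
        images: dict[str, SpectralImage] | dict[str, SyntheticScene] | None = None,
        genotypes: MarkerGenotypes | None = None) -> dict:
    """Full pipeline run writing all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if images is None:
            if not config.image_dir:
                raise ValueError("no images or image_dir given")
            images = config.image_dir
        phenotypes = run_phenotyping(images)
        band_io.write_table(phenotypes.reset_index(), out / "phenotypes.csv")
        if genotypes is None:
            if not config.genotypes_csv:
                return {"phenotypes": phenotypes}
            genotypes = band_io.read_genotypes(config.genotypes_csv)
        res = run_qtl(config, phenotypes, genotypes)
        band_io.write_table(res["map"].to_frame(), out / "map.csv")
        if len(res["qtl_table"]):
            band_io.write_table(res["qtl_table"], out / "qtl.csv")
        res["peak_lod_matrix"].to_csv(out / "peak_lod_matrix.csv")
        thr = {t: {"t5": v.threshold_5, "t10": v.threshold_10,
                   "n_perm": v.n_permutations, "seed": v.seed}
               for t, v in res["thresholds"].items()}
        (out / "thresholds.json").write_text(json.dumps(thr, indent=2))
        res["phenotypes"] = phenotypes
        return res
    finally:
        logger.removeHandler(handler)
        handler.close()
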