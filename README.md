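# leafqtl

Multispectral leaf-colour phenotyping and pseudo-testcross QTL mapping.

`leafqtl` turns top-down nine-band plant images (445, 500, 532, 550, 568,
676, 680, 700 and 800 nm; 10 nm bandwidth) and genome-wide marker tables of
an outbred F1 population into quantitative leaf-colour phenotypes and the
genetic loci underlying them.  It is aimed at plant researchers and breeders
who phenotype perennials through seasonal colour transitions (e.g. dormancy
break: red/brown over-wintering foliage turning green) and want to map that
variation without destructive sampling.

## What it computes

**Phenotyping.**  A pixel is classified as plant when its near-infrared
reflectance strictly exceeds its red reflectance (living vegetation's red
edge): `plant ⇔ I₈₀₀ > I₆₈₀`.  Cover area is the plant pixel count.  Each
plant's spectrum is the per-band median over its mask, standardized so the
nine bands sum to one,

  p_λ = median_λ / Σ_μ median_μ,

which removes day-to-day illumination scale.  From the proportions p_λ the
package evaluates fifteen vegetation indices — NDVI, SR, EVI, VARI, ViGreen,
SIPI, PSND, CARI, MCARI, ARI, RGRI, ACI, CRI1, CRI2 and PRI — covering
biomass, pigment, chlorophyll, anthocyanin, carotenoid and light-use-
efficiency axes, plus PC1/PC2 of a covariance PCA of the nine proportions.
That gives 27 traits per plant: area, 9 bands, 2 PCs, 15 indices.

**Genetics.**  Markers heterozygous in one parent and homozygous in the
other segregate 1:1 in the F1 and are informative for one parent's meioses
(the pseudo-testcross strategy), yielding a separate linkage map per parent:
two-point recombination fractions with phase resolution, single-linkage
grouping (r ≤ 0.35, LOD ≥ 3), exhaustive or greedy+2-opt ordering, and
Haldane (default) or Kosambi cM positions.  QTL scans use Haley–Knott
regression of a trait on conditional genotype probabilities over a 2 cM
pseudomarker grid,

  LOD = (n/2) · log₁₀(RSS₀ / RSS₁),

optionally as composite interval mapping with up to three forward-selected
marker cofactors and a 30 cM exclusion window.  Genome-wide significance is
empirical: the trait is permuted over individuals (cofactors re-selected
each time) and the 5%/10% quantiles of the max-LOD null distribution become
the thresholds.  Detected loci feed a four-class comparison (AH/AA/HH/HA
from the two markers nearest the top QTLs) with one-way ANOVA and Tukey
letters.

**Synthetic data.**  A first-class generator produces multispectral scenes
with exact ground-truth masks (green-peaked vs red-shifted anthocyanic leaf
profiles over a low-NIR background) and simulated 94-individual F1 crosses
with planted colour and NIR QTLs, so the whole chain is testable end to end.

## Worked example

```python
import numpy as np
from leafqtl import linkage_map, phenotyping, pipeline, qtl_scan, synthetic_data
from leafqtl.synthetic_data import QTL

# a simulated cross rendered as one image per F1 plant
cross  = synthetic_data.simulate_pseudo_testcross(n_f1=94, seed=1)
scenes = synthetic_data.render_population_images(
    cross, QTL("P2", 1, 30.0), nir_qtl=QTL("P1", 0, 30.0), seed=1)

phen  = pipeline.run_phenotyping(scenes)          # 94 plants x 27 traits
gmap  = linkage_map.build_maps(cross.genotypes)
probs = qtl_scan.genotype_probabilities(gmap, cross.genotypes)

y    = phen["VARI"].to_numpy()
scan = qtl_scan.cim_scan(probs, y, trait="VARI")
thr  = qtl_scan.permutation_thresholds(probs, y, n=200, seed=1, method="cim")
print(gmap.summary())
print(qtl_scan.significant_qtls(scan, thr))
```

prints

```
{'n_groups': 6, 'n_groups_P1': 3, 'n_groups_P2': 3, 'n_markers': 48,
 'total_length_cM': 442.79, 'mean_group_length_cM': 73.8,
 'mean_marker_spacing_cM': 10.54}
  trait group  position_cM       lod level
0  VARI  5.P2    24.221482  21.63345    5%
```

The map recovers the six simulated linkage groups (three per parent, eight
markers at 10 cM).  The VARI scan puts a single 5%-significant peak (LOD ≈
21.6) at 24 cM on the P2 group carrying the planted colour QTL (truth:
30 cM) — VARI is built from visible bands only, so it responds to the
green-vs-red leaf contrast that QTL controls.

A command-line layer mirrors the library: `leafqtl scenes`, `leafqtl cross`,
`leafqtl phenotype`, `leafqtl map`, `leafqtl run`.

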