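# Methods

This note records the models, conventions and parameter choices behind
`leafqtl`, and what the synthetic test bed does and does not establish about
real data.

## Imaging model and segmentation

Band planes are assumed co-registered (a static pot imaged from a fixed
mount) and are rescaled to [0, 1] by the integer full scale of their bit
depth (8 or 16 bit).  Gray values are treated as *relative* intensities, not
calibrated reflectance: the downstream sum-to-one standardization removes
any global scale, so radiometric calibration would only matter for
cross-instrument comparisons, which are out of scope.

Segmentation is the single rule `I₈₀₀ > I₆₈₀`, strictly: ties go to
background.  No morphological cleanup is applied by default (an optional
small-object removal flag exists).  The rule exploits the red edge of
living vegetation; it will mis-classify materials with NIR-bright surfaces
(some plastics, specular highlights) and shaded leaf regions whose NIR
drops below red — limitations inherited from the rule itself, not the
implementation.

Per-band medians over the mask use the mean-of-middle-two convention for
even counts.  A plant with an empty mask is an error at the plant level and
a logged skip at the population level; one degenerate capture never aborts
a run.

## Spectral standardization and indices

The phenotype unit is the vector p of nine proportions summing to one.
Standardization assumes illumination differences between capture days are
multiplicative and shared across bands.  That assumption is untestable from
single-camera data; if illumination were band-dependent (e.g. strongly
cloudy vs clear sky shifting the blue/NIR balance), the proportions would
absorb a spectral tilt, not just a scale.

All fifteen indices are evaluated on the standardized proportions,
including the non-ratio forms (CARI, MCARI, CRI1, CRI2, ARI) and EVI's
"+1" constant, which is therefore applied on the proportion scale.  This is
a deliberate faithful-to-protocol choice, not a radiometric one: absolute
values of the non-ratio indices depend on the standardization, but a
single illumination factor common to all plants cannot reorder plants on
any index, which is what comparative and QTL analyses consume.  Division
by zero in any one index yields NaN with a warning; the remaining indices
are still computed.

## PCA and correlations

PCA is computed on the covariance matrix of the nine proportions (they are
commensurable; correlation-scaling is available via `scale=True`).  Signs
of principal axes are arbitrary, so PC1 is pinned to a positive 676 nm
loading — high PC1 means red/brown foliage — and the other components to a
positive largest-magnitude loading.  PCA is fit per run (per measurement
date); pooling dates into one decomposition is possible by concatenating
tables but is not the default, since per-date fits keep the axes
interpretable when the population's spectral range shifts between seasons.
All reported correlations are Pearson (Spearman via flag), with two-sided
t-test p-values.

## Linkage mapping

Marker classification follows the pseudo-testcross design: informative for
P1 iff P1=H and P2=A (and conversely); markers heterozygous in both parents
(the 3:1 class) are excluded rather than mapped, keeping the two parental
maps clean.  Markers whose F1 segregation rejects 1:1 by chi-square at
α = 0.001 are excluded as distorted — distortion is a classic source of
pseudo-linkage.  Recombination fractions are estimated per phase (coupling
vs flipped coding) keeping the phase with r ≤ 0.5, on pairwise-complete
individuals (minimum 10), with LOD = R·log₁₀(r/0.5) + (n−R)·log₁₀((1−r)/0.5)
and the r→0 limit n·log₁₀2.

Grouping is single-linkage closure at r ≤ 0.35 and LOD ≥ 3 (common
defaults; singletons allowed).  Ordering minimises the sum of adjacent r:
exhaustively (up to reversal) for groups of ≤ 8 markers, greedy
nearest-neighbour seeded at the most distant pair plus 2-opt otherwise;
orientation is normalised by the lexicographically smaller terminal marker.
Haldane is the default map function, Kosambi selectable.  Adjacent r that
reaches 0.5 after ordering is clipped to 0.49 before distance conversion
rather than split — rare, and splitting mid-pipeline would renumber groups.

The Haldane transform of a binomial r̂ is convex, so estimated map lengths
run slightly long; at n = 94 and 10 cM spacing the inflation is ≈ 1% with a
between-seed SD of ≈ 6% of length.  Fragmentation into more groups than
chromosomes is expected at realistic marker densities and is left as-is;
no karyotype-guided merging is attempted.

## Genotype probabilities and QTL scans

A testcross has two genotype classes, so each linkage group is a two-state
Markov chain; with genotyping error set to zero, the conditional class
probability at any grid point depends only on the nearest observed flanking
markers, computed from the inverse map function of the flanking distances.
The grid is every 2 cM plus all marker positions.  Marker codings are
phase-aligned along the group so one consistent state runs the chromosome.
An individual untyped on a whole group gets flat 0.5 with a warning.

Haley–Knott regression uses the single regressor P(H):
LOD = (n/2)·log₁₀(RSS₀/RSS₁), implemented through partial correlation after
residualising trait and probabilities on the covariates; at fully observed
markers this reduces exactly to −(n/2)·log₁₀(1−R²) of the single-marker
regression (tested to 1e−10).  Complete-case per trait; a constant
probability column gives LOD 0 with a warning.

CIM selects up to 3 cofactors by forward regression on the mapped markers
(missing marker cells are filled with the marker mean for the cofactor
matrix only), and drops any cofactor within 30 cM of the scanned position
on the same group — "window 30" is interpreted as centimorgans.

Permutation thresholds shuffle the trait over individuals with genotypes
fixed, re-running the entire scan including cofactor re-selection (a valid
null), and take type-7 empirical quantiles of the genome-wide max LOD at
5%/10%.  Thresholds are per trait.  For plain HK with complete data the
permutation loop is evaluated as one correlation matrix product; a test
verifies it equals the scan-by-scan loop to 1e−10.  Defaults follow the
study protocol (2 cM grid, 1,000 permutations, 5%/10%, window 30); tests
and the acceptance script use 200 permutations, which moves a 5% threshold
by well under 0.15 LOD on these map sizes.

Contiguous supra-threshold runs collapse to one peak per run per group;
peaks clearing only the 10% threshold are labelled marginal.  The
four-class comparison (first letter = genotype at the first QTL's nearest
marker, second letter = second QTL's) uses one-way ANOVA plus Tukey HSD at
α = 0.01 with a deterministic compact letter display (highest mean = 'a').

## Synthetic data: what it emulates, and what it does not

Scenes are a disk or lobed blob of foreground spectrum over background.
The packaged profiles (in `_profiles.yaml`) encode: green leaves peaking at
550 nm with a strong 800 nm plateau; dormant/anthocyanic leaves with
depressed green and elevated 676–700 nm (anthocyanins absorb around
510–550 nm, so red-shifted reflectance); background with NIR at or below
red.  Per-pixel Gaussian noise (SD 0.01) is clipped to [0, 1].  Disk
rasterization is pixel-centres-at-integers with strict `x²+y²<r²` about the
image centre, making area oracles exact (radius 16 in 64×64 → 812 pixels).

Crosses simulate each parental chromosome as the same two-state Markov
chain the probability model assumes, with markers every 10 cM (8 per group,
3 groups per parent, n = 94 by default).  Planted QTLs act through the
genotype at their nearest marker — chosen for exact recoverability; a
latent between-marker QTL mode is available through `plant_qtl_effects`
positions.  Rendered populations tie phenotype to genotype through two
mechanisms chosen to mimic a spring dormancy-break population: a colour
QTL on a P2 group sets the green-vs-dormant mixture weight (A → 0.75,
H → 0.30, individual SD 0.2, clipped to [0,1]) and, through the weight,
the plant radius (10–16 px, greener = larger, so cover area and redness
are negatively associated); a NIR QTL on a P1 group adds 0.18 (individual
SD 0.035) to the 800 nm mean of the heterozygous class, moving
NIR-dependent biomass indices (SR, NDVI, EVI) without touching the visible
bands.  At these conditions the colour QTL shows LOD ≈ 17–28 on VARI and
the NIR QTL LOD ≈ 4.5–7 on SR — the latter the magnitude typical of a
single-date NIR locus at n = 94.

What passing these tests shows: the pipeline's operations implement their
stated mathematics, the scan is calibrated under the null, and planted
effects of realistic size are recovered through the full image→index→QTL
chain.  What they do not show: robustness to mis-registration, shadows,
overlapping plants, genotyping error (the probability model assumes none),
segregation-distorted regions, or non-multiplicative illumination changes —
none of which the generator emulates.  Note also that the synthetic NIR
axis is deliberately strong, so PC2 (the 800 nm axis) carries ≈ 25% of the
spectral variance in rendered populations, more than a field population
would typically show.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the study at n = 94 with 48
markers over 6 linkage groups, 200-permutation thresholds, 20-seed
end-to-end replication and a 200×200 null calibration — sizes chosen so the
whole battery completes in minutes on one CPU while keeping every rate
estimate's binomial error well inside its asserted band.
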