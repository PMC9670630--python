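# Methods

This note documents the models, estimators and design choices behind
`fluidnet`, in the order the pipeline runs them, together with what the
synthetic cohort generator does and does not emulate.

## Data model

Every platform dataset is a sample × assay `MeasurementMatrix` with a
per-cell status: `OBSERVED`, `BELOW_LOD` (numeric value retained),
`QC_FLAGGED` (value removed by a vendor QC warning), or `NOT_MEASURED`.
The three causes of missingness are kept distinct because the analyses
treat them differently: the missingness filter counts below-LOD cells
as missing, while harmonization retains below-LOD values as numbers and
treats only QC-flagged and never-measured cells as unavailable. No
operation silently converts `BELOW_LOD` to `OBSERVED`; consumers choose
a policy explicitly. Scales are declared (`linear` for RFU / 2^NPX /
TMT reporter intensity, `log2` for NPX) and conversions are exact
inverses on numeric cells. All joins are by sample/assay ID, never by
position.

File dialects are documented plain TSV (see `fluidnet.io`): a `!meta`
header block carries assay annotation; buffer wells use reserved
`BUFFER*` sample IDs; cell grammar encodes status (`<x` below-LOD,
`QC`, empty = not measured) so reader/writer round-trips are bit-exact.
Olink's predetermined LODs travel in an optional `lod_log2` metadata
row, since vendor files carry them out-of-band.

## QC

*S:N* is `(median sample signal − median buffer signal) / median buffer
signal`, evaluated on the linear scale at the assay's median sample
signal; negative values are legal and occur for assays reading below
buffer. *LOD* is `median(log2 buffer) + 3·SD(log2 buffer)` with SD on
the log2 scale; assays with fewer than two buffer replicates and no
supplied LOD are flagged, never silently passed.

The *missingness filter* keeps an assay iff its missing count is at
most `floor(0.75·n)` — at n = 36 that is 27, i.e. measured in at least
9 subjects.

The *empirical S:N threshold* scans the grid {0, 0.15, 0.25, 0.3, 0.35,
0.4, 0.45, 0.5, 0.625, 0.75, 1, 2, 4, 8}: at each cutoff the filtered
platform is paired with each other platform (exact UniProt first, then
gene symbol; among competing candidates the best-correlated one), the
within-subject Pearson correlation is computed per paired protein, and
the median over proteins is averaged over platform pairs. The smallest
cutoff attaining the maximum is selected (ties discard the least data).
At least five paired proteins are required per evaluated cutoff.

*Duplicate assays* (same UniProt, or same symbol when UniProt is empty)
are reduced to one representative by lexicographic criteria: highest
mean pairwise correlation with the other replicates, then highest
median signal, then largest log2 dynamic range (p95 − p5), then stable
ID order.

*Depletion censoring* matches proteins measured with and without
high-abundance depletion by UniProt; eligibility needs ≥ 9 paired
measurements and ≥ 3 per diagnostic group. A protein is censored when
the Pearson correlation of its paired log2 values is ≤ 0 or when its
AD−CT direction differs between the two matrices. The correlation is
taken over paired per-sample log2 values; a per-group difference
correlation was considered and rejected as less robust at these group
sizes.

## Harmonization

*Median polish* alternates row-then-column median sweeps (rows first,
fixed for determinism) until the largest median removed falls below
`tol = 1e-8` or 100 sweeps. The decomposition
`input = overall + row + column + residual` is exact to machine
precision, and converged residuals have row and column medians within
tolerance. A `nan_policy="omit"` variant uses `nanmedian` for
batch-level TMT missingness.

*TAMPOR batch correction*: each TMT reporter intensity is divided by
its batch's GIS value — geometric mean when a batch carries several GIS
channels, a choice made because the GIS is itself a pooled average and
the geometric mean is the natural combiner on the multiplicative scale
— then log2-transformed and median-polished. The "clean relative
abundance" form reinserts per-protein medians:
`2^(residual + protein median)`, all-positive like reporter abundance.
Proteins with no GIS in any batch are dropped with a report.

*Transposed TAMPOR* harmonizes the per-platform blocks of one fluid.
Anchors are the proteins present in every block after all filters. The
algorithm alternates (a) subtracting each sample's median over its
platform's anchor assays — the cross-platform central tendency, playing
the GIS role with samples treated as proteins — and (b) subtracting
each label's median over samples, to convergence (`tol = 1e-8`; the
sweep converges geometrically and may need ~10³ iterations, hence
`max_iter = 5000`). This one-loop formulation was chosen over
"center once, then polish the stacked matrix" because it guarantees
both output invariants simultaneously: anchor per-sample medians at
zero and label medians at zero. Blocks are restricted to complete-case
assays rather than imputed — below-LOD values are retained as numbers,
so only QC-flagged and truly absent cells cost an assay — which yields
the required no-missing-values property without inventing an imputation
model.

## Abundance analyses

Differential abundance is a per-assay two-sided t test on log2 values,
AD minus control, with **no median normalization** between groups: a
global shift of measured levels is a finding, not a nuisance. Welch's
unequal-variance form is the default (the equal-variance form is a
flag) because group variances are not assumed equal; assays with fewer
than 3 usable values in either group are skipped and reported.
Below-LOD values are included by default (policy flag exposed).
BH-adjusted p values are always emitted next to raw ones; the volcano
convention keeps raw p = 0.05 as the significance line.

Calibration to reference concentrations selects, per gene, the assay
with maximum mean signal, subtracts the buffer median, imputes missing
cells as half the minimum nonzero signal *for the geometric-mean step
only*, and rescales so the control-group geometric mean equals the
reference pg/L exactly. Cumulative curves: uncalibrated mode ranks
assays by mean background-subtracted signal and accumulates per-rank
group medians; calibrated mode ranks by reference concentration and
reports the group median of per-sample summed log10 concentrations of
all lesser-abundant proteins (left-truncated), which is monotone
nondecreasing. The top-fraction comparison takes the
`ceil(frac·n_assays)` strongest assays (default 5%) and t-tests
per-sample sums.

The power identity `min_detectable_rho(n, α, power) =
tanh((z_{1−α/2}+z_{power})/√(n−3))` uses the Fisher z approximation; it
is strictly decreasing in n and increasing in power, and a Monte-Carlo
check of the Pearson test confirms it at 2-dp accuracy.

## Networks

Biweight midcorrelation uses Tukey weights `w = (1−u²)²·1(|u|<1)` with
`u = (x−median)/(9·MAD)`; zero-MAD features fall back to the Pearson
standardization, and constant features are an error. Signed adjacency
is `((1+r)/2)^β` with β = 6.5 (CSF) and 11 (plasma), the values used
for these fluids in practice; a soft-threshold diagnostic is easy to
run but the defaults are not re-fit. TOM with mean denominator is
`(Σ_k a_ik a_kj + a_ij)/(mean(k_i,k_j)+1−a_ij)`; it is verified against
a brute-force triple loop to 1e-12.

Module detection is average-linkage clustering of TOM dissimilarity
with a dynamic recursive cut. The static component of the cut is
data-adaptive: merge heights of a modular dendrogram are bimodal (dense
within-module merges low; background and between-module joins high),
and the cut sits at the midpoint of the largest gap between consecutive
sorted heights above the 25th percentile, falling back to 99% of the
maximum height when no gap exists. Above the cut the tree is always
descended; below it a node splits only when both children reach the
minimum module size (10) and the merge-height gap exceeds a ladder
controlled by `deep_split` (4 = most aggressive). Sub-minimum siblings
are pruned to grey while descent continues. A PAM-like stage assigns
grey points to the nearest module by average dissimilarity when that
beats the overall mean dissimilarity. This is a documented variant of
the published dynamic hybrid cut, judged by planted-partition recovery
rather than label-for-label agreement with any particular
implementation; `pam_respects_dendro` is accepted for interface
compatibility but the variant does not consult the dendrogram during
absorption.

Eigenproteins are first principal components of standardized member
columns, unit-variance, sign-oriented to positive mean member
correlation (the orientation every downstream correlation relies on).
Modules merge while any eigenprotein pair has dissimilarity
(1 − correlation) below 0.07, recomputing after each merge. kME
consistency is enforced by iterating eigenprotein → kME → argmax
reassignment (floor `kme_min = 0.30` sends weak proteins to grey; no
floor is standard, so it is exposed in config) until a fixed point or
30 rounds; non-convergence is flagged, not hidden. Sample outliers are
flagged at standardized network connectivity below −2.5.

## Cross-network statistics

Label mapping applies the strict 6-step precedence (UniProt→MS,
symbol→MS, UniProt→Olink, UniProt→SomaScan, symbol→Olink,
symbol→SomaScan); each source protein maps to at most one target label
and records its step. Synthetic eigenproteins are PCs over mapped
member columns in the target data with the same orientation rule, plus
a Welch t test AD vs CT on the scores.

Module overlap uses the two-tailed Fisher exact test on the shared
gene-symbol background (the union of symbols present in both networks —
the background is exposed in config since conventions differ),
BH-corrected over all pairs; cell-type enrichment uses the one-tailed
(greater) form.

Preservation follows the permutation Z_summary recipe with five
statistics — two density (mean within-module correlation and adjacency
in the test data) and three connectivity (ref-vs-test correlation of
intramodular connectivity, of module-membership kME, and of the
correlation vectors). The full reference recipe aggregates more
statistics; these five cover both families and the set is
config-extensible. The null holds the reference module fixed and draws
the test-side membership at random (mirroring label permutation in the
test network); randomizing both sides would make the connectivity
statistics degenerate when test = reference. Z per statistic is
`(obs − null mean)/null SD`; `Z_density`/`Z_connectivity` are medians
of their families, `Z_summary` their mean; p is the upper normal tail
(preservation is one-sided), BH-corrected across modules, reported also
as `−log10(adjusted p)`. Default 500 permutations; tests use 40–100 for
speed.

`Z_slope` z-scores each module's eigenprotein within fluid, takes the
per-subject fluid-2 minus fluid-1 difference, and standardizes the
AD−CT difference of group means by `√(SE²_AD+SE²_CT)`. The
unstandardized difference is emitted alongside since either convention
appears in practice. Degenerate zero-variance cases are flagged as
infinite rather than returned silently.

## The synthetic cohort generator

The latent subject × protein log2 abundance is a baseline ladder
uniform on [4, 26] (> 6 orders of magnitude linear) plus a
fluid-specific protein term, module structure, AD effects and noise.
Eight modules of 25 proteins carry loadings U(0.8, 1.2) on independent
per-subject factor scores shared between fluids; AD shifts the scores
by (1.5, −1.5, 1.0, −1.0, 0.75, −0.75, 0.5, 0) eigenprotein SDs.
Member residual SD is 0.4, background 0.6. Clinical traits (T-tau,
p-Tau181, Aβ42, MoCA) are linear functions of the first module's score
plus noise — traits are generated *from* module scores, not vice versa,
so trait–eigenprotein correlations have known sign and magnitude for
recovery tests. In AD plasma a monotone attenuation (0.5 log2 at the
lowest abundance, linearly to zero at the 95th percentile) emulates the
global decrease of low-abundance plasma proteins; its shape is a free
design knob because no quantitative form is established.

The observation model adds per-platform per-sample offsets (log2 SD
0.5), per-assay platform biases (SD 1.0) and cell noise (SD 0.25). TMT
uses 4 batches of 9 subjects plus one GIS channel carrying the
all-sample average, per-(batch, protein) effects of SD 1.0, and
whole-batch dropouts at rate 0.08. Affinity platforms emit 6 buffer
replicates per assay (log2 SD 0.1); half of the non-anchor SomaScan CSF
assays are pure noise reading `buffer·(1+S:N)` with planted S:N
U(0.05, 0.4) — below the 0.45/0.5 grid region — while clean CSF assays
sit 3.5–7 log2 above buffer. Cells below the assay's true LOD are
marked below-LOD (value kept); random QC flags occur at rate 0.005.

The 150 anchor proteins are measured on all three platforms and are
excluded from the noise class — real anchors are, by definition, the
proteins that survive every platform's filters — sized so that ≥ 60
anchors per fluid survive QC (about 80 at the defaults; the real CSF
data had ~200, and the harmonization quality checks use a design at
that scale because central-tendency precision grows with
`√n_anchors`). Duplicate assays (10 extra SOMAmers, 5 duplicated Olink
assays) exercise the reduction rules.

Scaled-down defaults (~1050 assays per fluid instead of ~8000) keep a
full pipeline run near 10 s; the design accepts larger counts. What the
generator does **not** emulate: peptide-level MS structure, real
inter-protein correlation beyond the planted factors, non-Gaussian
heavy tails, plate/bridging structure within affinity platforms, or
cohort heterogeneity — so passing recovery tests demonstrate
correctness of the estimators under the assumed model, not performance
on any real cohort.

## Numerical and calibration notes

- All randomness flows through explicit seeds; a pipeline rerun with
  the same seed and config is bit-identical (floats are serialized with
  repr / %.10g).
- The per-assay false-positive rate under a fully null design
  (module shifts, plasma attenuation and platform offsets all zero) is
  5% within Monte-Carlo error, averaged over simulated cohorts; the SE
  is taken over cohorts because planted co-expression correlates assays
  within a cohort. With per-sample platform offsets left in, the naive
  per-assay test is anticonservative — which is precisely why the
  harmonized matrix, not the raw one, feeds the network stage.
- The critical |r| emitted by `correlate_with_traits` is the exact
  two-sided 5% point of the Pearson null at the attained n, so ~95% of
  null module–trait pairs fall below it.
- Problem sizes used in tests: cohorts of ~1050 assays/fluid, 5 seeds
  for recovery averages, 100 permutations for preservation
  calibration, 40–60 for unit-level checks.

## Known limitations

- The dynamic-cut variant can split one planted module into sub-modules
  on unfavourable draws; eigenprotein merging and kME reassignment
  usually repair this, but module counts may vary by ±2 across seeds.
- Transposed TAMPOR assumes every block shares the same sample set; the
  cohort member measured by only one platform must be dropped first.
- Preservation Z scores depend on the shared mapped universe; modules
  with < 3 mapped members are reported as NA.
- The generator's noise-class model makes S:N bimodal; real CSF aptamer
  data show a continuum, so threshold selection on real data may be
  less sharply identified than in simulation.
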