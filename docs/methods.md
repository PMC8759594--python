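# Methods

## The skeleton dot length metric

A FISH focus's dispersion score is obtained by the pipeline
binarize → dilate ×3 → skeletonize → measure:

1. **Binarize.** Default is the iterative-intermeans (IsoData-style)
   threshold computed directly on the intensity values: starting from the
   global mean, iterate `t ← (mean(x < t) + mean(x ≥ t)) / 2` to its fixed
   point; foreground is strictly above `t`. This mirrors the default
   auto-threshold of the common image-analysis stacks while remaining exactly
   auditable (the fixed point is asserted in tests rather than a binned
   histogram approximation). Otsu and fixed thresholds are selectable.
   A constant image has no automatic threshold and raises, directing the user
   to a fixed value; the composed pipeline treats a constant image as empty
   (no foci) rather than an error.
2. **Dilate.** Three passes of binary dilation with the 3×3 square element
   (8-neighborhood), the standard binary-dilate kernel. Dilation merges the
   sub-puncta of a moderately dispersed focus into one component and thickens
   thin structure so that thinning recovers a connected centerline.
3. **Skeletonize.** 2D topological thinning (Zhang's algorithm via
   scikit-image), which guarantees a width-1, connectivity-preserving
   skeleton. Pixel-level agreement with any particular host program is *not*
   a contract — thinning algorithms differ pixel-wise — but the properties
   that the classification depends on (width 1, component preservation,
   length under the edge convention below) are.
4. **Measure.** Foci are the 8-connected components of the dilated mask.
   The skeleton pixel graph joins 8-adjacent skeleton pixels with edges of
   weight 1 px (orthogonal) or √2 px (diagonal). A diagonal edge is dropped
   whenever either of its two orthogonal corner pixels is itself skeleton
   (the "chord rule"): in a configuration like an L-corner the diagonal
   would re-count a path already covered by two orthogonal steps. The rule
   makes "each step counted exactly once" deterministic, is symmetric under
   90° rotation, and reduces to the familiar orthogonal-1/diagonal-√2 path
   length on simple paths. A focus's skeleton dot length is the summed edge
   weight over all skeleton fragments inside its component, × pixel size.
   Branches are the skeleton segments delimited by endpoints (degree 1) and
   junctions (degree ≥ 3): per skeleton component with `E` retained edges
   and `n2` degree-2 pixels, `branches = E − n2`; an isolated pixel counts
   0 and a pure cycle 1. No pruning is applied, so spur branches count in
   both length and branch number.

Whether a multi-fragment focus should report the summed or the largest
fragment length is not uniquely determined by the phenotype; summation is
the default (a punctate, compartmentalized focus is *more* dispersed, and
per-focus crops naturally sum their fragments), and this is what
`total_skeleton_length` expresses for single-focus crops. Foci touching the
image border are retained but flagged for optional filtering.

## Categories, summaries, ranking

Default cutoffs are 0.75/1.25 µm (heterochromatin: compact/diffused/
dispersed) and 1.5/2.5 µm (euchromatin: compact-diffused/dispersed/
scattered). Printed ranges are taken closed on both ends with strict outer
inequalities, so a length exactly at a boundary falls in the middle bin —
a measure-zero choice on continuous data made explicit for determinism.
Whole-chromosome probes have no canonical edges and require user-supplied
bins.

Disperser ranking compares each allele's per-focus lengths against a
low-dispersing and a high-dispersing reference by one-sided Mann–Whitney
tests at α = 0.05: not significantly greater than the low reference → low;
otherwise not significantly less than the high reference → high; otherwise
medium. The low test takes precedence, so a degenerate configuration where
both references coincide classifies alleles as low. A plain tertile rule is
available where references are not meaningful. Ranks are 1..n ascending in
mean length with ties broken by allele name; the ordinal rank is the default
covariate for the expression screen ("rankings"), with the mean length
available as an alternative — when the mean-length vector is monotone in
rank the two produce identical hit sets.

## Spatial context

Nucleolar distance is edge-to-edge: the minimum Euclidean distance from any
pixel of a FISH component to any nucleolar pixel (0 for touching/overlap),
computed by an exact Euclidean distance transform of the nucleolar
background, calibrated by pixel size. Centroid distance would penalize
large nucleoli. Whether the original read-out was per focus or per cell is
not determinable; both modes are provided (`per="focus"`/`per="nucleus"`).
Nucleolar segmentation is an input mask, not re-derived.

## Puncta and PLA

LC3B puncta: threshold (iterative intermeans by default; a moment-preserving
"moments dark" threshold, computed on a 256-bin histogram after Tsai's
method, is provided because the named option has no equivalent in the
installed libraries), then remove particles with equivalent diameter
(2·√(area/π)·pixel size) below 1 µm — the sub-micrometre background
speckles — and count the rest.

Nucleus segmentation thresholds the DAPI channel, fills holes, and filters
8-connected components by border contact, area window (default 50–500 µm²)
and circularity 4πA/P² ≥ 0.8 (clipped at 1 to absorb digital-perimeter
bias). The numeric defaults are this package's declared values — the
workflows this emulates used unpublished thresholds — and all are
configurable. Merged ("too close") nuclei are operationalized as failures
of the circularity filter after fusion. PLA foci are assigned to the
nucleus containing their centroid, which is unambiguous for
boundary-straddling spots; foci outside all nuclei are counted and reported
so that per-nucleus counts plus ignored foci always equal the total.

Cell-cycle classes: EdU-positive (mean in-nucleus EdU intensity above a
threshold, default 0.3 on unit-normalized images) → S, regardless of DAPI.
EdU-negative nuclei are split on integrated DAPI intensity at the midpoint
of the two modes of their distribution, found by a 1D two-means fit; if the
two fitted clusters are not separated by more than the sum of their
within-cluster spreads the distribution is treated as unimodal and an
explicit split is required.

## 3C-qPCR quantification

Cp values are normalized per sample/replicate by subtracting the mean Cp
over all tested loci — a log2-scale centering that leaves all pairwise Cp
differences (hence all fold-changes) unchanged and makes the result
invariant to a constant shift of a replicate's Cp values. Fold-change is
`2^(Cp − Cp_origin)` exactly as stated for this assay; under the usual qPCR
convention a higher Cp means *less* product, so the sign convention is
surfaced in the result metadata (`sign_convention`) rather than silently
corrected. The origin locus's fold-change is exactly 1 in every replicate
by construction. Relative expression uses the standard ΔΔCp form
`2^−((Cp_t − Cp_ctrl)_t − (Cp_t − Cp_ctrl)_baseline)` with an internal
control gene. Condition comparison runs per-locus Welch t tests across
exactly two conditions with optional Holm–Šídák adjustment; the origin
locus, whose fold-changes are identically 1 in both conditions, reports
p = 1 rather than an undefined 0/0 statistic.

## Statistics

Mann–Whitney U is two-tailed by default and reports U = min(U₁, U₂). The
exact null distribution is used when min(n₁, n₂) ≤ 8 and there are no ties
(a feasible enumeration bound); otherwise the tie-corrected normal
approximation. The computational backends are scipy's; tests verify the
exact path against a full enumeration oracle for all n₁, n₂ ≤ 6 and the
asymptotic path by null simulation (at n = 20, 2000 simulations, the
rejection rate at α = 0.05 is ≈ 0.047 with binomial standard error ≈ 0.005).
Kruskal–Wallis uses the tie-corrected H with a χ² reference; Dunn's post
hoc z statistics on mean ranks (with the tie term Σ(t³−t)/(12(N−1)))
are computed in-package with optional Bonferroni adjustment. "Multiple t
tests" follow the behavior of the commercial software that popularized the
phrase: per-pair Welch t tests, optionally Holm–Šídák adjusted (the
"nonparametric multiple t test" wording found in figure legends is
self-contradictory, so a Mann–Whitney backend is also exposed; Welch is the
default and the backend used is recorded on every result). Stars follow
ns > 0.05, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.

## Synthetic scenes: what they emulate, and what they do not

Scenes are rendered at 0.1 µm/px by default — a plausible scale for a
63×/1.4 NA confocal with modest zoom; acquisition calibration is a free
parameter stored with every scene, never an assumed property of any real
dataset. Nuclei are ellipses (eccentricity ≤ 0.6) of 5 µm default
semi-major axis; FISH foci are clusters of `subpuncta_per_focus` isotropic
Gaussian sub-puncta (default 32 of 0.2 µm radius) scattered with standard
deviation `focus_spread_um` around the focus center — the dispersion knob.
Images are sums of Gaussians on a uniform background (default 0.05), clipped
to [0, 1], with additive Gaussian noise (default σ = 0.005) and 16-bit
quantization on disk. All randomness derives from one seed through
`SeedSequence` spawns, one stream per scene element, so identical parameters
reproduce bit-identical scenes.

Default choices worth stating:

* **Sub-puncta count (32).** A dispersed focus in this model must read out
  as *longer*, not merely as *more fragments*: with only a handful of
  sub-puncta, large spreads produce a few isolated dots whose skeletons are
  near-points, and the measured length would fall again after peaking at
  intermediate spread. A few dozen sub-puncta keep the cloud largely
  chained together after triple dilation across the whole spread range, so
  the measured mean length is strictly increasing in the knob — the
  defining property of a dispersion phenotype. This is a property of the
  generator's model, and it is asserted, not assumed, by the tests.
* **Noise σ = 0.005.** Iterative-intermeans thresholding fails on images
  whose foreground occupies a far smaller fraction of pixels than the noise
  tail — it converges inside the background mode (the same reason
  single-focus measurements in practice are made on high-SNR crops). The
  default noise keeps single-focus scenes within the regime where the
  default threshold is reliable; heavier noise is available but then a
  fixed threshold is the appropriate method.
* **Per-focus measurement of dispersed scenes.** Monotonicity and ranking
  checks generate one focus per scene and take the per-scene summed length
  (`total_skeleton_length`), the per-crop convention; whole-field runs with
  many foci per image are supported but conflate focus identity once clouds
  fragment.
* **PLA scenes** plant exact per-nucleus focus counts (foci separated by
  ≥ 6 spot-σ so thresholding resolves them), border nuclei centered on the
  frame edge, optional fused ellipse pairs for the merged-nuclei filter,
  and a balanced, shuffled 2N/4N mixture among EdU-negative nuclei (with
  ±5% multiplicative DAPI noise) so both DAPI modes always exist.
* **Expression matrices** standardize the covariate and add per-transcript
  Gaussian noise scaled as `noise_sd · √(1/r² − 1)`, so the expected
  Pearson correlation of a planted transcript is ±`target_abs_r` at
  `noise_sd = 1` and exactly ±1 at `noise_sd = 0`; decoy transcripts are
  random permutations of the covariate plus noise, giving the permutation
  null (P(|r| > 0.6) ≈ 0.025 at 15 alleles). Values are affinely mapped to
  a positive reads-per-million-like range, which leaves r untouched.
* **Cp tables** draw iid per-locus replicate noise around `base + delta`,
  so the per-locus replicate SD equals the requested `replicate_sd` and
  noiseless tables recover `2^delta` exactly.

Not modeled: point-spread-function realism, 3D structure (the analysis
operates on maximum projections), camera-noise physics beyond additive
Gaussian, chromatic or stage drift, and biological covariance between
channels. Passing tests therefore demonstrate the correctness of the
measurement and statistics on images whose ground truth is known — they do
not validate segmentation robustness on real microscope data, where
background structure, uneven illumination and focus variation dominate.

## Problem sizes

The test suite and the acceptance script run single-CPU in well under a
minute each stage: 210 oracle masks (≤ 32×32), 30 foci per spread condition
(four conditions), 2000 null simulations at n = 20, a 553 × 15 expression
matrix, and single PLA/puncta fields. These sizes give comfortable margins
for every property asserted (binomial/sampling error is quoted above where
it matters) while keeping the default run fast.

## Known limitations

* The intermeans threshold is global; scenes mixing very bright and very
  faint foci will drop the faint ones. Per-crop measurement or a fixed
  threshold is the remedy, as in practice.
* Branch counts on thinning artifacts: Zhang thinning can emit short spurs
  on rough blob boundaries; with `prune=none` semantics these count as
  branches, as intended, but branch numbers are therefore sensitive to
  boundary noise in a way lengths are not.
* `aggregate_and_compare` supports exactly two conditions (the comparison
  design it implements); multi-condition comparisons belong to
  Kruskal–Wallis/Dunn.
* The high/medium/low disperser rule depends on the chosen references; with
  weak references (small n) the one-sided tests lose power and alleles
  drift toward "low"/"high" by non-significance.
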