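# Methods

## Background and scope

`crossnet` implements a resting-state functional-connectivity (FC) analysis
for two-group studies of chronic pain, centred on the striatum. The analysis
compares healthy controls (CN) against patients with failed back surgery
syndrome (FBSS) and asks whether the coupling between the striatum network
and the rest of the brain carries information about the patient's pain
level. Its stages are:

1. **Extraction** — per-subject cleaning of 4D BOLD volumes and averaging
   into regional time series over an integer-label atlas.
2. **Connectivity** — Pearson FC matrices; within-network and cross-network
   connectivity strength (FCS); the per-subject striatum (STM) index.
3. **Group inference** — rank-sum tests on every network-pair FCS with
   Bonferroni correction, and an OLS regression of the STM index on the
   visual-analog pain score (PL).
4. **Seed connectivity** — voxelwise correlation with a small midbrain
   (periaqueductal grey) seed, Fisher-z transform, two-sample t-maps, and
   Monte-Carlo cluster-extent correction.

Registration, slice timing, motion correction and physiological-noise
regression are out of scope: input volumes are assumed spatially corrected,
and nuisance regressors (white matter, CSF, global mean) are accepted as
inputs rather than derived from tissue masks.

## Connectivity model

FC between regions *i* and *j* is the sample Pearson correlation of their
time series. FCS summaries are plain arithmetic means of correlations:

- within-network FCS over the n(n−1)/2 unordered pairs of one network
  (15 pairs for the six-region striatum: bilateral caudate, putamen,
  globus pallidus);
- cross-network FCS(A, B) over all |A|·|B| pairs between two disjoint
  networks;
- the **STM index** is the mean of the six cross-network FCS values between
  STM and the other six networks (MTN, DMN, SAN, TEP, HIP, DAN).

Correlations are averaged signed and untransformed; diagonals
(self-connections) are always excluded. An optional Fisher-average mode
(average artanh(r), back-transform) exists but is off by default, because
the FCS definitions are stated directly on correlations. Negative
correlations are kept as-is — no absolute value or thresholding.

The index is modelled against pain as `index = β₀ + β₁·PL + ε`, fitted by
OLS; R² and the two-sided t-test on β₁ (n−2 df) are reported. Records
lacking either variable are excluded and listed in the result.

## Group tests

Network-pair FCS values are compared between independent groups with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test. Note the *signed-rank*
test, sometimes named in this literature, is a paired test and cannot apply
to independent groups of unequal size; the rank-sum test is the coherent
choice and is what this package implements. For pooled sizes ≤ 12 with no
ties the p-value is exact (dynamic-programming enumeration of the rank-sum
null); otherwise the tie-corrected normal approximation with continuity
correction is used. The Bonferroni factor m is always the size of the batch
actually run (21 cross-network pairs, 15 within-striatum pairs), never a
global pool.

## Seed-based connectivity and cluster correction

The seed is a sphere of configurable diameter (default 4 mm, i.e. 2 mm
radius — taken literally) at mm coordinates (1, −29, −12). Because 2 mm can
be below the voxel spacing, the resolver falls back to the single nearest
voxel, so the seed is never empty. The seed series is the mean over seed
voxels; voxelwise Pearson r against it is mapped through the Fisher
transform m = ½·ln((1+r)/(1−r)) = artanh(r). (A typographically mangled
form of this formula circulates as "0.5ln(1+CC)/(1−CC)"; the artanh reading
is the standard, normality-improving one and is what is implemented.)
Values at |r| = 1 are clipped to 1 − 10⁻⁷ and counted.

Groups are compared with a pooled-variance two-sample t-test per voxel.
Familywise error is controlled AlphaSim-style: `n_iter` Gaussian
white-noise volumes are smoothed to the target FWHM, standardised,
thresholded two-sided at the voxel p, and the largest sign-pure cluster
recorded; the extent threshold is the smallest size whose null exceedance
frequency is ≤ α. Cluster connectivity defaults to face adjacency
(6-neighbour), with 18- and 26-neighbour rules available. Smoothness is
estimated from group residual maps by the variance-of-gradients estimator,
floored at one voxel (a sampled field cannot resolve sub-voxel smoothness;
the floor makes i.i.d. noise report ≈ the voxel size). Positive and
negative t-values are clustered separately, matching the convention of
reporting increases and decreases as distinct clusters. Voxelwise
thresholding is two-sided by default since both directions are of interest.

## Synthetic cohorts

The generator draws zero-mean Gaussian time series with a block correlation
matrix: `r_within` (default 0.5) inside a network, `r_between` (default
0.27, the control-group index level) across networks. Defaults mirror the
study conditions: 12 controls vs 10 patients, T = 175 retained volumes at
TR 2 s, 84 bilateral regions in seven networks.

Patients carry the effect in the covariance, not in relabelled outputs:
each patient's pain score is drawn uniformly from a 4.0–9.0 grid (step
0.5), a target index `β₀ + β₁·PL + N(0, σ_ε)` is formed (defaults
β₁ = −0.0311 and derived β₀ = 0.305, the values the packaged patient table
implies; σ_ε = 0.02), and the subject's striatum-to-other couplings are set
to that target, with within-striatum couplings lowered by the same absolute
amount. `delta_stm` (default 0.17) is the mean group-level reduction;
β₀ defaults to `r_between − delta_stm − β₁·mean(PL grid)` so the two
parameterisations agree, and `delta_stm = 0` disables the patient
modification entirely, giving an exchangeable null cohort. Any candidate
correlation matrix is eigenvalue-checked and, if indefinite, repaired by
uniform shrinkage of all off-diagonal couplings (factor 0.95 per step),
which preserves relative structure; the default block structure is PSD
without repair. All randomness flows from one seed through per-subject
substreams, so cohorts are bit-reproducible.

The volume generator paints parcel series into contiguous voxel blocks of a
low-resolution grid (default 24³ at 3 mm, affine centred on the origin so
standard-space-style coordinates resolve inside it), adding i.i.d. voxel
noise; an optional seed-to-target coupling increase can be planted in the
patient group to exercise the seed-FC chain with a known effect location.

What this emulates — and does not. The generator reproduces the pairwise
correlation structure, group difference and index–pain link that the
analysis measures. It has no hemodynamic response, no temporal
autocorrelation, no motion or physiological artefacts, and no anatomical
geometry; passing tests demonstrate correctness of the statistical
machinery under its assumed model, not robustness to real acquisition
artefacts.

## Packaged study tables

The two population tables ship with the package: 10 patients (pain score
and STM index; patient 7's index is missing due to imaging artifacts) and
13 controls (index only). Regressing the nine complete patient records
gives R² = 0.7596 and slope p = 0.00220. Two documented discrepancies in
the source material are preserved rather than resolved: the accompanying
text counts 12 controls while the control table lists 13 rows (all 13 are
kept); and the figure caption reporting the control index as mean 0.27,
SD 0.13 does not match recomputation from the 13 table rows
(0.2645 / 0.1183) under any single-row exclusion — the package always
reports recomputed values.

## Numerical choices

- Rank-sum exact p: doubled smaller tail, capped at 1; ties force the
  approximate branch.
- Degenerate regression (constant index): slope 0, R² reported as 0,
  p as 1.
- ROI means use an anchored mean (`v₀ + mean(v − v₀)`), exact when all
  voxels of a region share one series — this makes the zero-noise identity
  bit-exact.
- Despiking measures residuals from a least-squares line in robust SD units
  (1.4826·MAD) and squashes only points beyond 2.5 robust SDs through a
  saturating tanh map capped at 4 robust SDs; sub-threshold points are
  returned bit-identical. This reproduces the intent of standard despiking
  tools (bounded spikes) with explicit, documented math.
- Detrend order defaults to 1 (configurable 0–3); global-signal regression
  defaults on, with a flag to disable, since its use is contested.
- Zero-variance regions, empty networks, rank-deficient nuisance designs
  and out-of-grid seed centres raise errors naming the offending item.

## Problem sizes in the test suite

The acceptance-level checks run at: 100 synthetic cohorts of 22 subjects ×
175 time points × 84 regions for parameter recovery; 200 null two-group
datasets on a 24³ grid (plus a 1000-iterate null calibration) for the
familywise-error check at α = 0.05 (chosen over 0.01 so that 200 datasets
resolve the tail). These sizes give Monte-Carlo standard errors small
enough for the stated bounds while keeping the suite quick on one CPU.

## Known limitations

- The despike step is a mathematical reimplementation of the intent of the
  usual tooling, not a numerical clone of any specific program.
- Cluster-extent calibration simulates Gaussian fields; group t-maps with
  few subjects have slightly heavier tails, which the voxelwise p-value
  thresholding absorbs but which makes the correction approximate at very
  small n.
- The seed is resolved directly on the functional grid via its affine;
  co-registration of seeds defined on other grids is out of scope.
- No covariate adjustment (age, sex, medication), no FDR alternatives, no
  graph metrics, no dynamic FC.
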