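# Methods

## Scope

`alecontrast` implements two pipelines for testing an *A > B* contrast over
activation coordinates and a battery of metrics for comparing their results:

1. **CM** — one ALE meta-analysis over experiments reporting *A > B*
   directly, with analytic voxel-wise inference and cluster-level FWE
   correction;
2. **MC** — a permutation contrast between the *A > baseline* and
   *B > baseline* ALE meta-analyses, inclusively masked by the main effect
   of the condition of interest.

Everything runs on synthetic coordinate datasets with known ground truth;
no anatomical template or external imaging data is required or bundled.

## ALE

**Kernel.** A focus reported by an experiment with *n* participants is
modelled as an isotropic Gaussian with
`FWHM(n) = sqrt(subject_fwhm²/n + template_fwhm²)`.  The defaults derive
from the standard empirical estimates of coordinate displacement — 11.6 mm
between-subject and 5.7 mm between-template Euclidean displacement —
converted to FWHM via `FWHM = E|d| · sqrt(8 ln 2) / (2 sqrt(2/π))`, giving
`subject_fwhm ≈ 17.12 mm` and `template_fwhm ≈ 8.41 mm`.  These constants
are configuration, not claims: every test in the suite depends only on the
qualitative behaviour of `FWHM(n)` (strictly decreasing in *n*, bounded
below by the template term), never on the numeric values.

**Truncation.** Kernels are evaluated on the voxel lattice out to the radius
where the Gaussian falls below 1e-5 of its peak, then renormalised to unit
mass.  This keeps MA construction linear in the number of foci; the mass
discarded is below 1e-3 of the kernel.

**MA maps and ALE.** Per experiment, the modelled activation map is the
voxel-wise *maximum* over per-focus kernels (a non-additive rule: an
experiment reporting several nearby peaks is not more convincing than one
reporting a single peak there).  ALE is the probabilistic union
`1 − ∏(1 − MAᵢ)` across experiments.  Foci are mapped to voxels by
nearest-voxel rounding under the inverse affine; foci outside the mask are
kept (their kernel may still overlap the mask) and logged.

To make results invariant to the order in which experiments are listed —
float multiplication is commutative but not associative — the union product
sorts its factors per voxel, and the null-histogram combination (below)
processes experiment histograms in a canonical byte-sorted order.  Fixed
input + fixed seed therefore reproduces every map bit-exactly.

**Analytic null.** Under the null of random spatial association, the ALE
score at a voxel is the union of one independently drawn in-mask MA value
per experiment.  The null distribution is built on a histogram with bin
width 1e-4 on [0, 1]: each experiment contributes the histogram of its
in-mask MA values, and histograms are combined pairwise by depositing the
product mass of bins *a* and *m* at the floor bin of `1 − (1−a)(1−m)`.
Floor deposition makes p-values conservative at bin edges.  Survival
probabilities are right-continuous; z-scores are the standard-normal
quantile of `1 − p`, capped in magnitude at the value for one part in the
histogram resolution so they are always finite.

The Monte-Carlo check of this null (in the test suite and acceptance
script) samples one in-mask MA value per experiment and combines draws under
the same binning convention; agreement is then limited only by sampling
error (≤ 0.01 at 50,000 draws).  Comparing against *unbinned* draws instead
mixes in the discretization offset, which is concentrated entirely at ALE
magnitudes below ~1e-3 (negligible scores far from any threshold) and
reaches ~0.015 there; in the inferential tail (p < 0.1) binned and unbinned
agree to ~0.003.

**Cluster-level FWE.** The observed ALE map is thresholded at the
cluster-forming p (< 0.001 by default, evaluated against the analytic null)
and 26-connected components are labelled (the FSL clustering convention).
For each permutation, every focus of every experiment is relocated to a
uniformly random in-mask voxel — focus counts and sample sizes preserved —
ALE is recomputed and thresholded at the same ALE cut-off, and the maximum
cluster size recorded.  A cluster is significant iff its size strictly
exceeds the empirical 95th-percentile order statistic of that null.

Because focus counts and kernel widths are held constant and the analytic
null already models random placement, the permuted datasets share the real
data's null up to boundary and max-rule edge effects; the cluster-forming
ALE cut-off is therefore computed once from the real data rather than
re-derived per permutation.  Permutation randomness uses one master seed
with deterministically derived per-permutation child seeds.

*Calibration note.* On the reduced grids used here, supra-threshold noise
clusters are small integers (sizes 1–3), so the strictly-greater rule loses
the tie mass at the 95th-percentile value and the realized family-wise
error rate is conservative: ~0.02–0.04 rather than 0.05 (measured over 50
noise-only replicates).  The same mechanism operates, more mildly, at full
scale; it is a property of the published procedure, not of this
implementation, and is not corrected for.

## Meta-contrast (MC)

The observed statistic is the voxel-wise ALE difference of the two
main-effect meta-analyses.  Its null pools the experiments of both
conditions, shuffles, and splits them back into pseudo-groups of the
original sizes — exchangeability of whole experiments; an experiment's foci
and sample size always travel together.  With `n_perm` permutations,

    p(v) = (1 + #{perm diff ≥ observed diff}) / (1 + n_perm)

(the add-one correction keeps p positive and z finite).  A voxel is
significant iff `p < α` (0.05, one-sided *A > B*; the reverse contrast is a
second call with the datasets swapped), it lies in the main-effect mask,
and it belongs to a 26-connected significant component of ≥ k = 5 voxels
(extent filtering after masking).

**Main-effect mask.** The inclusive mask defaults to the condition of
interest's own main effect at uncorrected p < 0.001; the cFWE-corrected map
is available via `mask_kind="cfwe"`.  The choice is logged on every run
because it decides which voxels can ever reach significance.  Note the
structural consequence: the mask is *selected on the same data* as the
contrast, so within-mask rejections under exchangeability exceed the
nominal voxel-wise α near the mask's edges.  This is inherent to the
published MC procedure, and is the reason the shared-activation analysis
below scores detection at the true centre rather than anywhere in a
neighbourhood.

## Similarity metrics

All comparisons operate on the *significant* (thresholded, binarized) maps —
what a meta-analytic paper would report — not on unthresholded statistics.
Voxel level: Jaccard, sensitivity `|CM∩MC|/|CM|`, precision `|CM∩MC|/|MC|`.
Cluster level: a 26-connected cluster counts as overlapping if it shares at
least one voxel with the other map; sensitivity and precision are the
overlapping fractions on each side.  Peak level: local maxima (≥ all 26
neighbours, value above threshold) of each side's uncorrected thresholded
z map, greedily thinned in descending order to a minimum mutual distance of
8 mm with ties broken by lexicographic voxel index; the report carries the
median Euclidean distance from each CM peak to its nearest MC peak and vice
versa.  Peak thresholds default to each map's own uncorrected criterion
(p < 0.001 for CM z maps, α for MC z maps) and are settings, since the z
threshold for MC peak extraction is not canonically fixed.  Ratios with a
zero denominator are reported as NaN with a machine-readable reason code,
never silently as 0.

## Synthetic data

The generator emulates the structure of real coordinate corpora, which are
typically shareable only on request: per-experiment focus lists with
variable sample size, ground-truth convergence centres shared or
differential between conditions, Gaussian jitter around centres, and
uniform noise foci in the mask.

Defaults (chosen once, as magnitudes typical of task-fMRI coordinate
corpora): jitter sd 5 mm; 2–10 noise foci per experiment; n_subjects
uniform on [10, 40]; signal hit rate 0.6; analysis volume a 24³ box at 4 mm
(a 96 mm cube) with an all-true mask.  Jittered foci falling outside the
mask are *resampled*, not projected, to avoid boundary pile-up.  Noise foci
are drawn without replacement over in-mask voxel centres so experiments
never contain duplicate coordinates.  Randomness is hierarchical
(scenario seed → condition → experiment index), so the same seed is
bit-reproducible and extending a dataset never perturbs existing
experiments.

Presets:

* `differential_only` — one centre with hit rate 0.6 in condition A and the
  difference experiments, 0 in B; 30 experiments per dataset.  Both CM and
  MC should recover the centre.
* `shared_activation` — the same centre with hit rate 0.6 in *all three*
  datasets; 30 experiments each.  CM should flag the centre (the difference
  experiments converge there); MC should not (no difference in convergence).
* `null` — no centres, noise only, 25 experiments per dataset; A and B are
  exchangeable, the premise of the MC permutation null.

What these simulations do **not** emulate: publication bias, study-specific
smoothing and thresholding, correlated multi-peak reporting, anatomically
realistic grey-matter geometry, and between-condition confounds.  Passing
the calibration and recovery checks therefore validates the statistical
machinery under its own assumptions, not the behaviour of the method on any
particular real literature.

## Validation design

The acceptance layer (tests/test_acceptance.py, scripts/acceptance.py)
checks, at reduced problem sizes chosen as the package's desk-scale
defaults (16³–24³ grids at 4 mm, 1000 permutations, 10–50 replicates):

* brute-force oracle equality of MA maps and the ALE union (≤ 1e-12);
* analytic-null vs sampling-null survival agreement (≤ 0.01 at 50k draws);
* cFWE family-wise false-positive rate on noise (0.05 ± 0.03 band; realized
  conservatively low, see the calibration note above);
* MC voxel-wise type-I error under exchangeability (0.05 ± 0.015);
* MC recovery of a differential centre (significant cluster within 10 mm of
  truth in ≥ 90% of replicates);
* the shared-activation asymmetry: the centre voxel is flagged by CM in
  ≥ 90% and by MC in ≤ 10% of replicates.  Detection is scored *at the true
  centre voxel* for both methods: MC's rare significant voxels in this
  regime sit 2–8 mm off-centre at main-effect-mask edges — the
  extent/shift effects noted above — while the shared centre itself stays
  undetected, which is precisely the mechanism under test;
* exact agreement of all counting metrics with naive enumeration, and of
  peak distances with an exhaustive nearest-neighbour oracle (float
  tolerance 1e-9);
* bit-exact reproducibility of a full evaluation under a fixed seed.

## Numerical choices and degenerate inputs

* Histogram bin width 1e-4; ALE-to-bin assignment uses `floor(x/bw + 1e-9)`
  so values at bin edges land in the edge's bin despite float error.
* z caps: analytic maps at the quantile of one part in the null resolution
  (≈ 3.72); contrast maps at the quantile of `1/(1+n_perm)`.
* Empty permutation threshold maps record maximum cluster size 0; if no
  histogram bin reaches below the cluster-forming p, nothing is significant.
* Merged experiments with conflicting sample sizes take the maximum
  (conservative: never narrows the kernel relative to any constituent row);
  the conflict is logged.
* Talairach-space inputs are rejected outright; no coordinate conversion.
* `n_perm < 100` is refused (quantiles too unreliable); a pooled contrast
  with fewer than 4 experiments is refused (degenerate null).

## Limitations

* Kernel constants are literature-standard defaults; exact numeric parity
  with other ALE implementations is not claimed.
* The cluster-forming cut-off for cFWE permutations reuses the real data's
  analytic null (see above) — exact only up to boundary/max-rule effects.
* One-sided contrasts only; balanced (equal-n) contrasts, conjunction
  analyses, and meta-regression covariates are out of scope.
* The box-shaped synthetic mask has more corner/edge voxels with reduced
  kernel coverage than a brain-shaped mask; this slightly deflates the MC
  voxel-wise rejection rate (ties at uncovered voxels give p = 1).
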