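# alecontrast

Coordinate-based meta-analyses of neuroimaging studies can test a contrast
between two conditions in two quite different ways, and the two do not ask
the same question:

* **CM (contrast-meta)** — a standard ALE (activation likelihood estimation)
  meta-analysis across experiments that report the *A > B* contrast directly.
  It finds **consistent activation differences**: where do individual
  within-subject contrasts converge?
* **MC (meta-contrast)** — a permutation contrast between two ALE
  meta-analyses of main effects (*A > baseline* vs *B > baseline*).  It finds
  **differences in consistent activation**: where does across-study
  convergence differ between the two literatures?

`alecontrast` implements both pipelines end to end, the voxel-, cluster-,
and peak-level similarity metrics for comparing their thresholded result
maps, and a synthetic-focus generator with known ground truth, so that the
whole apparatus can be validated without access to any proprietary
coordinate corpus.

## The model

Each reported activation focus is treated as the centre of an isotropic 3-D
Gaussian capturing the spatial uncertainty of reported coordinates.  Its
width at sample size *n* is

    FWHM(n) = sqrt( FWHM_subj² / n + FWHM_tmpl² )

so larger studies contribute tighter kernels, bounded below by the
between-template term.  Per experiment, a modelled activation (MA) map takes
the voxel-wise **maximum** over its foci's kernels (nearby foci do not
stack), and the ALE score is the probabilistic union across experiments:

    ALE(v) = 1 − ∏ᵢ (1 − MAᵢ(v))

Voxel-wise inference uses the analytic null of random spatial association,
built by non-linear histogram convolution of the experiments' in-mask MA
value distributions; cluster-level FWE correction compares observed cluster
sizes (cluster-forming p < 0.001, 26-connectivity) with the maximum cluster
sizes obtained when all foci are relocated uniformly at random in the mask.

The meta-contrast tests the voxel-wise ALE difference against a
pool–shuffle–split permutation null (whole experiments are exchanged, never
individual foci), thresholds at posterior probability > 0.95 (p < 0.05,
one-sided), masks inclusively by the condition of interest's own main
effect, and applies a cluster extent threshold of k = 5 voxels.

Similarity of the two binarized result maps is quantified by

    Jaccard   = |CM ∩ MC| / |CM ∪ MC|
    Sensitivity = |CM ∩ MC| / |CM|
    Precision   = |CM ∩ MC| / |MC|

plus cluster-level overlap fractions and median nearest-peak distances in
both directions (local maxima at a minimum mutual distance of 8 mm).

## Worked example

Run a full head-to-head evaluation on the built-in `differential_only`
scenario (one convergence centre hit by 60% of condition-A and difference
experiments, never by condition B, plus uniform noise foci):

```sh
alecontrast evaluate --preset differential_only --seed 11 --n-perm 1000 --outdir out/
```

prints (abridged):

```json
{
  "jaccard": 0.3854166666666667,
  "voxel_sensitivity": 0.46835443037974683,
  "voxel_precision": 0.6851851851851852,
  "n_voxels_cm": 79,
  "n_voxels_mc": 54,
  "n_clusters_cm": 1,
  "n_clusters_mc": 1,
  "n_clusters_cm_overlapping": 1,
  "n_clusters_mc_overlapping": 1,
  "cluster_sensitivity": 1.0,
  "cluster_precision": 1.0,
  "median_dist_cm_to_mc_mm": 8.0,
  "median_dist_mc_to_cm_mm": 29.76263497554426
}
```

Both analyses recover the planted centre as a single significant cluster
(cluster sensitivity and precision 1.0).  The contrast-meta network (79
voxels) is larger than the meta-contrast network (54 voxels) and covers
more of it than vice versa (precision 0.69 vs sensitivity 0.47) — the
qualitative pattern expected when the contrast of interest is carried by a
genuine differential convergence centre: MC is the less sensitive of the
two.  `out/` contains all NIfTI maps,
the cluster table, peak lists, the JSON report, and a manifest sufficient to
reproduce every output bit-exactly.

The library surface mirrors the CLI: `synthetic_data.preset(...)`,
`ale_core.cfwe_threshold(...)`, `contrast.run_mc(...)`,
`compare.compare_maps(...)`, `pipeline.run_evaluation(...)`.

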