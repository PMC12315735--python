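"""Activation likelihood estimation: MA maps, ALE scores, analytic null, cFWE.

Each focus is modelled as the centre of an isotropic 3-D Gaussian whose width
reflects the spatial uncertainty of reported coordinates; the between-subject
component shrinks with the experiment's sample size.  Per experiment, a
modelled activation (MA) map takes the voxel-wise *maximum* over the foci's
Gaussians (non-additive: nearby foci do not stack).  ALE is the voxel-wise
probabilistic union across experiments, ALE = 1 - prod_i (1 - MA_i).

Inference: ALE scores are compared against an analytic null of random spatial
association, built by a non-linear histogram convolution of the experiments'
in-mask MA value distributions.  Cluster-level FWE correction compares
observed cluster sizes with the maximum cluster size obtained when every
focus is relocated uniformly at random within the mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .exceptions import ValidationError
from .io_coords import BrainGrid, CoordinateDataset, Experiment

log = logging.getLogger(__name__)

# Conversion from the literature's empirical Euclidean displacement estimates
# (mean displacement of corresponding points) to a Gaussian FWHM:
# FWHM = sigma * sqrt(8 ln 2) and E|displacement| = 2 sigma sqrt(2/pi).
_EUCLIDEAN_TO_FWHM = math.sqrt(8.0 * math.log(2.0)) / (2.0 * math.sqrt(2.0 / math.pi))

#: Between-participant spatial uncertainty at n = 1, as FWHM in mm
#: (11.6 mm empirical Euclidean displacement).
SUBJECT_FWHM_MM = 11.6 * _EUCLIDEAN_TO_FWHM
#: Between-template spatial uncertainty, as FWHM in mm (5.7 mm displacement).
TEMPLATE_FWHM_MM = 5.7 * _EUCLIDEAN_TO_FWHM

#: 26-neighbourhood connectivity structure (FSL cluster convention).
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

DEFAULT_BIN_WIDTH = 1e-4


@dataclass(frozen=True)
class KernelModel:
    """Gaussian kernel model for coordinate uncertainty.

    Effective FWHM at sample size n is
    ``sqrt(subject_fwhm_mm**2 / n + template_fwhm_mm**2)`` — strictly
    decreasing in n and bounded below by the template term.  The stencil is
    truncated where the Gaussian falls below ``truncation_level`` of its peak
    and renormalised to unit mass.
    """

    subject_fwhm_mm: float = SUBJECT_FWHM_MM
    template_fwhm_mm: float = TEMPLATE_FWHM_MM
    truncation_level: float = 1e-5

    def __post_init__(self) -> None:
        if self.subject_fwhm_mm <= 0 or self.template_fwhm_mm <= 0:
            raise ValidationError("kernel FWHM components must be positive")
        if not 0 < self.truncation_level < 1:
            raise ValidationError("truncation_level must be in (0, 1)")

    def fwhm_mm(self, n_subjects: int) -> float:
        if n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        return math.sqrt(self.subject_fwhm_mm**2 / n_subjects + self.template_fwhm_mm**2)

    def sigma_mm(self, n_subjects: int) -> float:
        return self.fwhm_mm(n_subjects) / math.sqrt(8.0 * math.log(2.0))

    def truncation_radius_mm(self, n_subjects: int) -> float:
        """Radius where the untruncated Gaussian reaches truncation_level of peak."""
        return self.sigma_mm(n_subjects) * math.sqrt(-2.0 * math.log(self.truncation_level))


@dataclass(frozen=True)
class MaMap:
    """Per-experiment modelled activation map (values in [0, 1]) on a grid."""

    values: np.ndarray
    source: Experiment


@dataclass(frozen=True)
class AleNull:
    """Histogram null distribution of ALE scores under spatial independence.

    ``bin_edges`` has one more entry than ``probabilities``; the mass of bin i
    represents ALE values in [edges[i], edges[i+1]) (floor convention, hence
    conservative p-values at bin edges).
    """

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or probs.ndim != 1 or len(edges) != len(probs) + 1:
            raise ValidationError("AleNull: need len(bin_edges) == len(probabilities) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("AleNull: bin_edges must be strictly increasing")
        if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("AleNull: probabilities must be non-negative and sum to 1")
        edges.setflags(write=False)
        probs.setflags(write=False)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)

    @property
    def survival(self) -> np.ndarray:
        """sf[i] = P(null ALE falls in bin i or above); monotone non-increasing."""
        return np.cumsum(self.probabilities[::-1])[::-1]

    def _bin_index(self, ale: np.ndarray) -> np.ndarray:
        ale = np.asarray(ale, dtype=float)
        nudge = 1e-9 * (self.bin_edges[-1] - self.bin_edges[0])
        idx = np.searchsorted(self.bin_edges, ale + nudge, side="right") - 1
        return np.clip(idx, 0, len(self.probabilities) - 1)

    def p_values(self, ale: np.ndarray) -> np.ndarray:
        """Right-continuous survival probability of each ALE score."""
        return self.survival[self._bin_index(ale)]

    def ale_threshold(self, p: float) -> float:
        """Smallest bin lower edge whose survival probability is < p.

        Returns +inf when no bin reaches below p (nothing can be significant).
        """
        below = np.nonzero(self.survival < p)[0]
        if len(below) == 0:
            return np.inf
        return float(self.bin_edges[below[0]])


@dataclass(frozen=True)
class AleResult:
    """Full output of one ALE meta-analysis with cluster-FWE correction."""

    grid: BrainGrid
    ale: np.ndarray
    p_uncorrected: np.ndarray
    z: np.ndarray
    null: AleNull
    cluster_labels: np.ndarray
    significant_cluster_ids: frozenset[int]
    cluster_size_null: np.ndarray
    cluster_forming_p: float
    fwe_p: float
    seed: int | None = None

    @property
    def significant_mask(self) -> np.ndarray:
        """Boolean volume of voxels in cFWE-significant clusters."""
        if not self.significant_cluster_ids:
            return np.zeros(self.grid.shape, dtype=bool)
        return np.isin(self.cluster_labels, sorted(self.significant_cluster_ids))

    @property
    def uncorrected_mask(self) -> np.ndarray:
        """Boolean volume of voxels passing the cluster-forming threshold."""
        return self.cluster_labels > 0

    def cluster_sizes(self) -> dict[int, int]:
        labels = self.cluster_labels
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


# ---------------------------------------------------------------------------
# kernels and MA maps
# ---------------------------------------------------------------------------

_stencil_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def kernel_profile(
    n_subjects: int, kernel: KernelModel, grid: BrainGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated, unit-mass Gaussian stencil on the voxel lattice.

    Returns ``(stencil, radii)`` where ``stencil`` has shape
    ``2 * radii + 1`` (voxels) and sums to 1; ``radii`` is the per-axis
    half-extent in voxels.  Offsets are converted to mm through the affine's
    linear part, so anisotropic voxels are handled.
    """
    lin = grid.affine[:3, :3]
    key = (int(n_subjects), kernel, lin.tobytes())
    hit = _stencil_cache.get(key)
    if hit is not None:
        return hit

    sigma = kernel.sigma_mm(n_subjects)
    r_mm = kernel.truncation_radius_mm(n_subjects)
    radii = np.maximum(np.ceil(r_mm / grid.voxel_sizes).astype(int), 1)
    axes = [np.arange(-r, r + 1) for r in radii]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    offsets = np.stack([ii, jj, kk], axis=-1).astype(float)
    mm = offsets @ lin.T
    d2 = np.sum(mm * mm, axis=-1)
    stencil = np.exp(-d2 / (2.0 * sigma**2))
    stencil[d2 > r_mm**2] = 0.0
    stencil /= stencil.sum()
    stencil.setflags(write=False)
    radii.setflags(write=False)
    _stencil_cache[key] = (stencil, radii)
    return stencil, radii


def _paste_max(out: np.ndarray, stencil: np.ndarray, centre: np.ndarray, radii: np.ndarray) -> None:
    """out[region] = max(out[region], stencil), clipped at the grid border."""
    lo = centre - radii
    hi = centre + radii + 1
    lo_c0 = max(lo[0], 0); lo_c1 = max(lo[1], 0); lo_c2 = max(lo[2], 0)
    hi_c0 = min(hi[0], out.shape[0]); hi_c1 = min(hi[1], out.shape[1]); hi_c2 = min(hi[2], out.shape[2])
    if hi_c0 <= lo_c0 or hi_c1 <= lo_c1 or hi_c2 <= lo_c2:
        return
    region = out[lo_c0:hi_c0, lo_c1:hi_c1, lo_c2:hi_c2]
    sten = stencil[lo_c0 - lo[0]: hi_c0 - lo[0],
                   lo_c1 - lo[1]: hi_c1 - lo[1],
                   lo_c2 - lo[2]: hi_c2 - lo[2]]
    np.maximum(region, sten, out=region)


def _ma_values(
    foci_ijk: np.ndarray,
    stencil: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int, int],
    out: np.ndarray | None = None,
) -> np.ndarray:
    if out is None:
        out = np.zeros(shape, dtype=float)
    else:
        out.fill(0.0)
    for centre in foci_ijk:
        _paste_max(out, stencil, centre, radii)
    return out


def build_ma_map(experiment: Experiment, kernel: KernelModel, grid: BrainGrid) -> MaMap:
    """Modelled activation map: voxel-wise max over the experiment's foci."""
    stencil, radii = kernel_profile(experiment.n_subjects, kernel, grid)
    ijk = grid.mm_to_voxel(experiment.foci)
    inside = grid.contains_mm(experiment.foci)
    if not inside.all():
        log.info(
            "experiment %r: %d focus/foci outside the mask (kept; kernels may "
            "still overlap the mask)", experiment.study_id, int((~inside).sum()),
        )
    values = _ma_values(ijk, stencil, radii, grid.shape)
    return MaMap(values=values, source=experiment)


def compute_ale(ma_maps: list[MaMap] | list[np.ndarray]) -> np.ndarray:
    """ALE(v) = 1 - prod_i (1 - MA_i(v)) — probabilistic union across experiments."""
    if not ma_maps:
        raise ValidationError("compute_ale: need at least one MA map")
    arrays = [m.values if isinstance(m, MaMap) else np.asarray(m) for m in ma_maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValidationError("compute_ale: MA maps on different grids")
    if len(arrays) == 1:  # union of one is the MA map itself, exactly
        return arrays[0].astype(float, copy=True)
    # sort factors per voxel so the product is bit-identical under any
    # permutation of the experiment list
    om = np.sort(np.stack([1.0 - a for a in arrays]), axis=0)
    return 1.0 - om.prod(axis=0)


# ---------------------------------------------------------------------------
# analytic null
# ---------------------------------------------------------------------------

def _histogram_ma(values_in_mask: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor(values_in_mask / bin_width + 1e-9).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / counts.sum()


def analytic_null(
    ma_maps: list[MaMap] | list[np.ndarray],
    grid: BrainGrid,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> AleNull:
    """Null ALE distribution under spatial independence of experiments.

    Each experiment contributes the histogram of its in-mask MA values;
    histograms are combined pairwise through the union formula
    ``1 - (1 - a)(1 - m)``, with the combined mass deposited at the floor bin
    (conservative p-values).
    """
    if not ma_maps:
        raise ValidationError("analytic_null: need at least one MA map")
    if not 0 < bin_width <= 0.01:
        raise ValidationError("analytic_null: bin_width must be in (0, 0.01]")
    n_bins = int(round(1.0 / bin_width)) + 1  # covers [0, 1] inclusive
    edges = np.arange(n_bins + 1) * bin_width
    values = np.arange(n_bins) * bin_width  # bin lower edges, the represented values

    hists = []
    for m in ma_maps:
        arr = m.values if isinstance(m, MaMap) else np.asarray(m)
        if arr.shape != grid.shape:
            raise ValidationError("analytic_null: MA map shape does not match grid")
        hists.append(_histogram_ma(arr[grid.mask], bin_width, n_bins))
    # canonical combination order: sequential floor-binned combination is not
    # associative at the ulp level, so sort histograms to make the null
    # bit-identical under experiment reordering
    hists.sort(key=lambda h: h.tobytes())

    acc: np.ndarray | None = None
    for h in hists:
        if acc is None:
            acc = h
            continue
        nz_a = np.nonzero(acc)[0]
        nz_m = np.nonzero(h)[0]
        combined = 1.0 - np.outer(1.0 - values[nz_a], 1.0 - values[nz_m])
        idx = np.floor(combined / bin_width + 1e-9).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        weights = np.outer(acc[nz_a], h[nz_m])
        acc = np.bincount(idx.ravel(), weights=weights.ravel(), minlength=n_bins)
    acc = acc / acc.sum()  # guard against accumulated float drift
    return AleNull(bin_edges=edges, probabilities=acc)


def ale_to_p(ale: np.ndarray, null: AleNull) -> tuple[np.ndarray, np.ndarray]:
    """Map ALE scores to uncorrected p-values and z-scores.

    z is the standard-normal quantile of 1 - p, capped in magnitude at the
    value corresponding to one part in the null's resolution (1 / n_bins), so
    it is always finite.
    """
    p = null.p_values(ale)
    p_min = 1.0 / len(null.probabilities)
    z_cap = float(norm.isf(p_min))
    z = norm.isf(np.clip(p, p_min, 1.0 - 1e-16))
    z = np.clip(z, -z_cap, z_cap)
    return p, z


# ---------------------------------------------------------------------------
# cluster-level FWE
# ---------------------------------------------------------------------------

def label_clusters(
    mask: np.ndarray, structure: np.ndarray = CONNECTIVITY_26
) -> tuple[np.ndarray, int]:
    """26-connected component labelling of a boolean volume."""
    labels, n = ndimage.label(mask, structure=structure)
    return labels, int(n)


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = label_clusters(supra)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cfwe_threshold(
    dataset: CoordinateDataset,
    kernel: KernelModel,
    grid: BrainGrid,
    cluster_forming_p: float = 0.001,
    fwe_p: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AleResult:
    """ALE analysis with cluster-level family-wise error correction.

    The observed ALE map is thresholded at the cluster-forming p (against the
    analytic null) and 26-connected clusters are labelled.  The null of
    maximum cluster sizes is built by relocating every focus of every
    experiment to a uniformly random in-mask voxel (focus counts and sample
    sizes preserved), recomputing ALE, and thresholding at the same ALE
    cut-off.  A cluster is significant iff its size strictly exceeds the
    empirical (1 - fwe_p) order statistic of that null.
    """
    if n_perm < 100:
        raise ValidationError("cfwe_threshold: n_perm must be >= 100")
    if not 0 < cluster_forming_p < 1 or not 0 < fwe_p < 1:
        raise ValidationError("cfwe_threshold: thresholds must lie in (0, 1)")

    ma_maps = [build_ma_map(e, kernel, grid) for e in dataset.experiments]
    ale = compute_ale(ma_maps)
    null = analytic_null(ma_maps, grid)
    p, z = ale_to_p(ale, null)

    supra = (p < cluster_forming_p) & grid.mask
    labels, n_clusters = label_clusters(supra)

    # permutation null of maximum cluster sizes under random focus relocation
    ale_cut = null.ale_threshold(cluster_forming_p)
    mask_ijk = grid.mask_indices
    n_mask = len(mask_ijk)
    stencils = {
        e.n_subjects: kernel_profile(e.n_subjects, kernel, grid)
        for e in dataset.experiments
    }
    foci_counts = [e.n_foci for e in dataset.experiments]
    ns = [e.n_subjects for e in dataset.experiments]

    child_seeds = np.random.SeedSequence(seed).spawn(n_perm)
    cluster_size_null = np.zeros(n_perm, dtype=int)
    buf = np.empty(grid.shape, dtype=float)
    acc = np.empty(grid.shape, dtype=float)
    if np.isfinite(ale_cut):
        for i, ss in enumerate(child_seeds):
            rng = np.random.default_rng(ss)
            acc.fill(1.0)
            for n_sub, n_foci in zip(ns, foci_counts):
                stencil, radii = stencils[n_sub]
                draws = mask_ijk[rng.integers(0, n_mask, size=n_foci)]
                _ma_values(draws, stencil, radii, grid.shape, out=buf)
                acc *= 1.0 - buf
            supra_perm = (acc <= 1.0 - ale_cut + 1e-12) & grid.mask
            cluster_size_null[i] = _max_cluster_size(supra_perm)

    order = int(np.ceil((1.0 - fwe_p) * n_perm)) - 1
    cutoff = int(np.sort(cluster_size_null)[order])
    sizes = np.bincount(labels.ravel())
    significant = frozenset(
        int(cid) for cid in range(1, n_clusters + 1) if sizes[cid] > cutoff
    )
    log.info(
        "cFWE: %d cluster(s) at p<%g, null %g-quantile max size = %d, %d significant",
        n_clusters, cluster_forming_p, 1 - fwe_p, cutoff, len(significant),
    )
    return AleResult(
        grid=grid, ale=ale, p_uncorrected=p, z=z, null=null,
        cluster_labels=labels, significant_cluster_ids=significant,
        cluster_size_null=cluster_size_null,
        cluster_forming_p=cluster_forming_p, fwe_p=fwe_p, seed=seed,
    )


def ale_uncorrected(
    dataset: CoordinateDataset, kernel: KernelModel, grid: BrainGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray, AleNull]:
    """ALE with analytic-null p/z but no cluster-FWE permutations.

    Used for the main-effect maps that serve as inclusive masks in the
    meta-analytic contrast.  Returns (ale, p, z, null).
    """
    ma_maps = [build_ma_map(e, kernel, grid) for e in dataset.experiments]
    ale = compute_ale(ma_maps)
    null = analytic_null(ma_maps, grid)
    p, z = ale_to_p(ale, null)
    return ale, p, z, null
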