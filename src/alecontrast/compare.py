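"""Similarity metrics between thresholded statistical maps.

Three levels of comparison between the binarized significant-voxel maps of a
contrast-meta (CM) and a meta-contrast (MC):

* voxel level — Jaccard |CM∩MC| / |CM∪MC|, sensitivity |CM∩MC| / |CM|,
  precision |CM∩MC| / |MC|;
* cluster level — fraction of 26-connected clusters of one map that share at
  least one voxel with the other map;
* peak level — local maxima of each side's uncorrected thresholded z map,
  thinned to a minimum mutual distance, and the median Euclidean distance
  from each peak to the nearest peak of the opposite map, in both directions.

Undefined ratios (division by zero) are reported as NaN with a machine
readable reason code, never silently as 0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .ale_core import CONNECTIVITY_26, AleResult, label_clusters
from .contrast import ContrastResult
from .exceptions import ValidationError
from .io_coords import BrainGrid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinaryMap:
    """Binarized significance map on a grid (significant = True)."""

    significant: np.ndarray
    grid: BrainGrid
    label: str = "other"

    def __post_init__(self) -> None:
        sig = np.asarray(self.significant, dtype=bool)
        if sig.shape != self.grid.shape:
            raise ValidationError("BinaryMap: shape does not match grid")
        object.__setattr__(self, "significant", sig)

    @property
    def n_voxels(self) -> int:
        return int(self.significant.sum())


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of a statistic map: (mm coordinate, value) pairs."""

    peaks: tuple[tuple[tuple[float, float, float], float], ...]
    min_separation_mm: float

    def __post_init__(self) -> None:
        coords = self.coordinates
        if len(coords) > 1:
            d = cdist(coords, coords)
            np.fill_diagonal(d, np.inf)
            if d.min() < self.min_separation_mm - 1e-9:
                raise ValidationError("PeakSet: peaks closer than min_separation_mm")
        if any(not np.isfinite(v) for _, v in self.peaks):
            raise ValidationError("PeakSet: non-finite peak value")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([c for c, _ in self.peaks], dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.peaks)


def _warn_undefined(metric: str, reason: str) -> float:
    warnings.warn(f"{metric} undefined: {reason}", RuntimeWarning, stacklevel=3)
    return float("nan")


def jaccard(a: BinaryMap, b: BinaryMap) -> float:
    """|a ∩ b| / |a ∪ b|; NaN when both maps are empty."""
    if a.grid.shape != b.grid.shape:
        raise ValidationError("jaccard: maps on different grids")
    union = int((a.significant | b.significant).sum())
    if union == 0:
        return _warn_undefined("jaccard", "both maps empty")
    inter = int((a.significant & b.significant).sum())
    return inter / union


def voxel_sensitivity(cm: BinaryMap, mc: BinaryMap) -> float:
    """|CM ∩ MC| / |CM| — how much of the CM network MC recovers."""
    n_cm = cm.n_voxels
    if n_cm == 0:
        return _warn_undefined("voxel_sensitivity", "CM map empty")
    return int((cm.significant & mc.significant).sum()) / n_cm


def voxel_precision(cm: BinaryMap, mc: BinaryMap) -> float:
    """|CM ∩ MC| / |MC| — how much of MC lies inside the CM network."""
    n_mc = mc.n_voxels
    if n_mc == 0:
        return _warn_undefined("voxel_precision", "MC map empty")
    return int((cm.significant & mc.significant).sum()) / n_mc


@dataclass(frozen=True)
class ClusterOverlap:
    n_cm: int
    n_mc: int
    n_cm_overlapping: int
    n_mc_overlapping: int
    cluster_sensitivity: float
    cluster_precision: float


def cluster_overlap(cm: BinaryMap, mc: BinaryMap, structure: np.ndarray = CONNECTIVITY_26) -> ClusterOverlap:
    """Count clusters of each map that share at least one voxel with the other.

    cluster_sensitivity = overlapping CM clusters / total CM clusters;
    cluster_precision   = overlapping MC clusters / total MC clusters.
    """
    if cm.grid.shape != mc.grid.shape:
        raise ValidationError("cluster_overlap: maps on different grids")

    def _count(side: BinaryMap, other: BinaryMap) -> tuple[int, int]:
        labels, n = label_clusters(side.significant, structure)
        if n == 0:
            return 0, 0
        overlapping_ids = np.unique(labels[other.significant & (labels > 0)])
        return n, int(len(overlapping_ids))

    n_cm, cm_over = _count(cm, mc)
    n_mc, mc_over = _count(mc, cm)
    sens = cm_over / n_cm if n_cm else _warn_undefined("cluster_sensitivity", "CM has no clusters")
    prec = mc_over / n_mc if n_mc else _warn_undefined("cluster_precision", "MC has no clusters")
    return ClusterOverlap(n_cm, n_mc, cm_over, mc_over, sens, prec)


def extract_peaks(
    stat_map: np.ndarray,
    grid: BrainGrid,
    threshold: float,
    min_distance_mm: float = 8.0,
) -> PeakSet:
    """Supra-threshold local maxima, thinned to a minimum mutual distance.

    A candidate voxel's value must exceed ``threshold``, lie in the mask, and
    be >= all of its 26 neighbours.  Candidates are accepted greedily in
    descending value order (ties broken by lexicographic voxel index); a
    candidate within ``min_distance_mm`` of an accepted peak is discarded.
    An empty result is not an error.
    """
    if not np.isfinite(threshold):
        raise ValidationError("extract_peaks: threshold must be finite")
    if min_distance_mm <= 0:
        raise ValidationError("extract_peaks: min_distance_mm must be positive")
    stat_map = np.asarray(stat_map, dtype=float)
    if stat_map.shape != grid.shape:
        raise ValidationError("extract_peaks: stat map shape does not match grid")

    local_max = ndimage.maximum_filter(
        stat_map, footprint=CONNECTIVITY_26, mode="constant", cval=-np.inf
    )
    cand = (stat_map > threshold) & (stat_map >= local_max) & grid.mask
    idx = np.argwhere(cand)
    if len(idx) == 0:
        return PeakSet(peaks=(), min_separation_mm=min_distance_mm)
    vals = stat_map[cand]
    # descending value; ties by lexicographic voxel index (argwhere is C-ordered)
    order = np.lexsort((np.arange(len(vals)), -vals))
    idx = idx[order]
    vals = vals[order]
    mm = grid.voxel_to_mm(idx)

    accepted: list[int] = []
    for i in range(len(idx)):
        if accepted:
            d = np.linalg.norm(mm[accepted] - mm[i], axis=1)
            if d.min() < min_distance_mm:
                continue
        accepted.append(i)
    peaks = tuple((tuple(map(float, mm[i])), float(vals[i])) for i in accepted)
    return PeakSet(peaks=peaks, min_separation_mm=min_distance_mm)


def peak_distances(from_set: PeakSet, to_set: PeakSet) -> float:
    """Median over from-peaks of the Euclidean mm distance to the nearest to-peak."""
    if len(from_set) == 0:
        return _warn_undefined("peak_distances", "empty from_set")
    if len(to_set) == 0:
        return _warn_undefined("peak_distances", "empty to_set")
    d = cdist(from_set.coordinates, to_set.coordinates)
    return float(np.median(d.min(axis=1)))


@dataclass(frozen=True)
class ComparisonReport:
    """All voxel-, cluster-, and peak-level CM-vs-MC similarity metrics.

    Distances are directional: ``median_dist_cm_to_mc_mm`` is from CM peaks to
    their nearest MC peak, and vice versa.  NaN fields carry a reason code in
    ``undefined_reasons``.
    """

    jaccard: float
    voxel_sensitivity: float
    voxel_precision: float
    n_voxels_cm: int
    n_voxels_mc: int
    n_clusters_cm: int
    n_clusters_mc: int
    n_clusters_cm_overlapping: int
    n_clusters_mc_overlapping: int
    cluster_sensitivity: float
    cluster_precision: float
    median_dist_cm_to_mc_mm: float
    median_dist_mc_to_cm_mm: float
    peaks_cm: tuple = ()
    peaks_mc: tuple = ()
    undefined_reasons: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        for key, val in list(d.items()):
            if isinstance(val, float) and np.isnan(val):
                d[key] = None  # strict JSON; reason retained in undefined_reasons
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        for key, val in list(d.items()):
            if val is None:
                d[key] = float("nan")
        d["peaks_cm"] = tuple((tuple(c), v) for c, v in d["peaks_cm"])
        d["peaks_mc"] = tuple((tuple(c), v) for c, v in d["peaks_mc"])
        return cls(**d)

    def peak_table_tsv(self) -> str:
        lines = ["x\ty\tz\tvalue\tmap"]
        for label, peaks in (("CM", self.peaks_cm), ("MC", self.peaks_mc)):
            for (x, y, z), v in peaks:
                lines.append(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{v:.6g}\t{label}")
        return "\n".join(lines) + "\n"


def compare_maps(
    cm_result: AleResult,
    mc_result: ContrastResult,
    min_peak_distance_mm: float = 8.0,
    cm_peak_p: float = 0.001,
    mc_peak_alpha: float = 0.05,
) -> ComparisonReport:
    """Assemble the full voxel/cluster/peak comparison of a CM and an MC run.

    Binarization uses each side's *significant* map (cFWE clusters for CM,
    masked+extent-filtered permutation map for MC).  Peaks are extracted from
    each side's own uncorrected thresholded z map: CM at uncorrected
    p < ``cm_peak_p``, MC at permutation p < ``mc_peak_alpha``.
    """
    grid = cm_result.grid
    if grid.shape != mc_result.grid.shape:
        raise ValidationError("compare_maps: results on different grids")
    cm_bin = BinaryMap(cm_result.significant_mask, grid, label="CM")
    mc_bin = BinaryMap(mc_result.significant, grid, label="MC")

    reasons: dict[str, str] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        jac = jaccard(cm_bin, mc_bin) if (cm_bin.n_voxels or mc_bin.n_voxels) else float("nan")
        if not (cm_bin.n_voxels or mc_bin.n_voxels):
            reasons["jaccard"] = "both_maps_empty"
        sens = voxel_sensitivity(cm_bin, mc_bin)
        prec = voxel_precision(cm_bin, mc_bin)
        clus = cluster_overlap(cm_bin, mc_bin)

        cm_stat = np.where(cm_result.p_uncorrected < cm_peak_p, cm_result.z, 0.0)
        mc_stat = np.where(mc_result.p_perm < mc_peak_alpha, mc_result.z, 0.0)
        cm_peaks = extract_peaks(cm_stat, grid, threshold=0.0, min_distance_mm=min_peak_distance_mm)
        mc_peaks = extract_peaks(mc_stat, grid, threshold=0.0, min_distance_mm=min_peak_distance_mm)
        d_cm_mc = peak_distances(cm_peaks, mc_peaks)
        d_mc_cm = peak_distances(mc_peaks, cm_peaks)
    for w in caught:
        msg = str(w.message)
        if "undefined" in msg:
            name = msg.split(" undefined")[0]
            reasons.setdefault(name, msg.split(": ", 1)[-1].replace(" ", "_"))

    if np.isnan(sens):
        reasons.setdefault("voxel_sensitivity", "cm_map_empty")
    if np.isnan(prec):
        reasons.setdefault("voxel_precision", "mc_map_empty")

    return ComparisonReport(
        jaccard=jac,
        voxel_sensitivity=sens,
        voxel_precision=prec,
        n_voxels_cm=cm_bin.n_voxels,
        n_voxels_mc=mc_bin.n_voxels,
        n_clusters_cm=clus.n_cm,
        n_clusters_mc=clus.n_mc,
        n_clusters_cm_overlapping=clus.n_cm_overlapping,
        n_clusters_mc_overlapping=clus.n_mc_overlapping,
        cluster_sensitivity=clus.cluster_sensitivity,
        cluster_precision=clus.cluster_precision,
        median_dist_cm_to_mc_mm=d_cm_mc,
        median_dist_mc_to_cm_mm=d_mc_cm,
        peaks_cm=cm_peaks.peaks,
        peaks_mc=mc_peaks.peaks,
        undefined_reasons=reasons,
    )
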