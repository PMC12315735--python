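"""Meta-analytic contrast (MC): permutation test between two ALE analyses.

The observed statistic is the voxel-wise ALE difference between the two
conditions' meta-analyses.  Its null is built by pooling the experiments of
both conditions, shuffling, and splitting them back into pseudo-groups of the
original sizes — exchangeability of whole experiments, never of individual
foci.  Significance requires the observed difference to beat the permutation
null (one-sided, condition A > condition B), membership in the condition of
interest's own main-effect mask, and a minimum cluster extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from . import ale_core
from .ale_core import CONNECTIVITY_26, KernelModel, label_clusters
from .exceptions import ValidationError
from .io_coords import BrainGrid, CoordinateDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastResult:
    """Output of one directed meta-analytic contrast (A > B)."""

    grid: BrainGrid
    ale_diff: np.ndarray
    p_perm: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    direction: str
    main_effect_mask: np.ndarray | None = None
    n_perm: int | None = None
    alpha: float | None = None
    k: int | None = None
    seed: int | None = None


def _one_minus_ma_rows(
    datasets: list[CoordinateDataset], kernel: KernelModel, grid: BrainGrid
) -> np.ndarray:
    """(n_experiments, n_mask) array of 1 - MA restricted to in-mask voxels."""
    mask = grid.mask
    rows = []
    for ds in datasets:
        for exp in ds.experiments:
            ma = ale_core.build_ma_map(exp, kernel, grid).values
            rows.append(1.0 - ma[mask])
    return np.array(rows)


def ale_difference(
    dataset_a: CoordinateDataset,
    dataset_b: CoordinateDataset,
    kernel: KernelModel,
    grid: BrainGrid,
) -> np.ndarray:
    """Voxel-wise ALE(A) - ALE(B) over the full grid (0 outside the mask)."""
    ma_a = [ale_core.build_ma_map(e, kernel, grid) for e in dataset_a.experiments]
    ma_b = [ale_core.build_ma_map(e, kernel, grid) for e in dataset_b.experiments]
    diff = ale_core.compute_ale(ma_a) - ale_core.compute_ale(ma_b)
    return np.where(grid.mask, diff, 0.0)


def contrast_permutation_test(
    dataset_a: CoordinateDataset,
    dataset_b: CoordinateDataset,
    kernel: KernelModel,
    grid: BrainGrid,
    main_effect_mask: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    k: int = 5,
    seed: int = 0,
) -> ContrastResult:
    """Pool-shuffle-split permutation test of ALE(A) - ALE(B), one-sided A > B.

    p_perm uses the add-one small-sample correction
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` so that p is never zero and z
    stays finite.  A voxel is significant iff p_perm < alpha, it lies inside
    ``main_effect_mask``, and it belongs to a 26-connected significant
    component of at least ``k`` voxels (extent filtering after masking).
    """
    if n_perm < 100:
        raise ValidationError("contrast_permutation_test: n_perm must be >= 100")
    if k < 1:
        raise ValidationError("contrast_permutation_test: k must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("contrast_permutation_test: alpha must be in (0, 1)")
    main_effect_mask = np.asarray(main_effect_mask, dtype=bool)
    if main_effect_mask.shape != grid.shape:
        raise ValidationError("contrast_permutation_test: main-effect mask grid mismatch")
    n_a, n_b = len(dataset_a), len(dataset_b)
    if n_a + n_b < 4:
        raise ValidationError("contrast_permutation_test: fewer than 4 experiments pooled")

    om = _one_minus_ma_rows([dataset_a, dataset_b], kernel, grid)  # (n_a+n_b, n_mask)
    prod_a = om[:n_a].prod(axis=0)
    prod_b = om[n_a:].prod(axis=0)
    diff_obs = prod_b - prod_a  # = ALE_A - ALE_B

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_total = n_a + n_b
    count_ge = np.zeros(diff_obs.shape, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        pa = om[perm[:n_a]].prod(axis=0)
        pb = om[perm[n_a:]].prod(axis=0)
        count_ge += (pb - pa) >= diff_obs
    p_mask = (1.0 + count_ge) / (1.0 + n_perm)

    p_min = 1.0 / (1.0 + n_perm)
    z_cap = float(norm.isf(p_min))
    z_mask = np.clip(norm.isf(np.clip(p_mask, p_min, 1.0 - 1e-16)), -z_cap, z_cap)

    mask = grid.mask
    p_full = np.ones(grid.shape, dtype=float)
    p_full[mask] = p_mask
    z_full = np.zeros(grid.shape, dtype=float)
    z_full[mask] = z_mask
    diff_full = np.zeros(grid.shape, dtype=float)
    diff_full[mask] = diff_obs

    candidate = (p_full < alpha) & mask & main_effect_mask
    labels, n_comp = label_clusters(candidate, CONNECTIVITY_26)
    significant = np.zeros(grid.shape, dtype=bool)
    if n_comp:
        sizes = np.bincount(labels.ravel())
        keep = np.nonzero(sizes >= k)[0]
        keep = keep[keep > 0]
        if len(keep):
            significant = np.isin(labels, keep)

    return ContrastResult(
        grid=grid, ale_diff=diff_full, p_perm=p_full, z=z_full,
        significant=significant,
        direction=f"{dataset_a.label} > {dataset_b.label}",
        main_effect_mask=main_effect_mask,
        n_perm=n_perm, alpha=alpha, k=k, seed=seed,
    )


def run_mc(
    dataset_a: CoordinateDataset,
    dataset_b: CoordinateDataset,
    kernel: KernelModel,
    grid: BrainGrid,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    k: int = 5,
    seed: int = 0,
    mask_kind: str = "uncorrected",
    mask_p: float = 0.001,
    fwe_p: float = 0.05,
    cfwe_n_perm: int = 1000,
) -> ContrastResult:
    """Full meta-analytic contrast A > B with the main-effect inclusive mask.

    ``mask_kind='uncorrected'`` (default) masks by the condition-of-interest
    main effect thresholded at uncorrected p < ``mask_p``;
    ``mask_kind='cfwe'`` uses that main effect's cFWE-significant clusters
    instead.  The mask choice is logged because it materially changes which
    contrast voxels can ever reach significance.
    """
    if mask_kind == "uncorrected":
        _, p_a, _, _ = ale_core.ale_uncorrected(dataset_a, kernel, grid)
        main_mask = (p_a < mask_p) & grid.mask
    elif mask_kind == "cfwe":
        res_a = ale_core.cfwe_threshold(
            dataset_a, kernel, grid, cluster_forming_p=mask_p,
            fwe_p=fwe_p, n_perm=cfwe_n_perm, seed=seed,
        )
        main_mask = res_a.significant_mask
    else:
        raise ValidationError(f"run_mc: unknown mask_kind {mask_kind!r}")
    log.info(
        "MC %s > %s: main-effect mask kind=%s (p<%g), %d voxels",
        dataset_a.label, dataset_b.label, mask_kind, mask_p, int(main_mask.sum()),
    )
    return contrast_permutation_test(
        dataset_a, dataset_b, kernel, grid, main_effect_mask=main_mask,
        n_perm=n_perm, alpha=alpha, k=k, seed=seed,
    )
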