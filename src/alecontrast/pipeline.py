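"""End-to-end evaluation: run CM, run MC, compare, with full provenance.

CM (contrast-meta) is a standard ALE meta-analysis across experiments that
report the A > B contrast directly; MC (meta-contrast) is the permutation
contrast between the A > baseline and B > baseline meta-analyses.  Both are
driven from a single declarative configuration and written out with a
manifest (config echo, seeds, version, per-stage wall time) sufficient to
reproduce every map bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np

from . import __version__
from . import ale_core, compare, contrast, io_coords, synthetic_data
from .ale_core import AleResult, KernelModel
from .compare import ComparisonReport
from .contrast import ContrastResult
from .exceptions import ValidationError
from .io_coords import BrainGrid, CoordinateDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationConfig:
    """Everything needed for one CM-vs-MC evaluation.

    Datasets come either from a synthetic scenario preset (``preset``) or
    from CSV paths (``dataset_a/b/diff_path``); the grid from ``mask_path``
    or the default synthetic box.  Reduced-scale defaults (4 mm grid,
    n_perm = 1000) keep a full evaluation interactive; set ``n_perm=10000``
    and a 2 mm mask for production-scale runs.
    """

    preset: str | None = None
    dataset_a_path: str | None = None
    dataset_b_path: str | None = None
    dataset_diff_path: str | None = None
    mask_path: str | None = None
    subject_fwhm_mm: float = ale_core.SUBJECT_FWHM_MM
    template_fwhm_mm: float = ale_core.TEMPLATE_FWHM_MM
    cluster_forming_p: float = 0.001
    fwe_p: float = 0.05
    alpha: float = 0.05
    k: int = 5
    min_peak_distance_mm: float = 8.0
    mc_mask_kind: str = "uncorrected"
    n_perm: int = 1000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name in ("cluster_forming_p", "fwe_p", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.preset is None and not (
            self.dataset_a_path and self.dataset_b_path and self.dataset_diff_path
        ):
            raise ValidationError("need either a preset or all three dataset paths")

    @property
    def kernel(self) -> KernelModel:
        return KernelModel(
            subject_fwhm_mm=self.subject_fwhm_mm, template_fwhm_mm=self.template_fwhm_mm
        )


def load_inputs(
    config: EvaluationConfig,
) -> tuple[CoordinateDataset, CoordinateDataset, CoordinateDataset, BrainGrid]:
    """Resolve (dataset_a, dataset_b, dataset_diff, grid) from the config."""
    if config.mask_path:
        grid = io_coords.load_grid(config.mask_path)
    else:
        grid = synthetic_data.make_box_grid()
    if config.preset:
        spec = synthetic_data.preset(config.preset, seed=config.seed)
        ds_a = synthetic_data.generate_dataset(spec, "A", grid)
        ds_b = synthetic_data.generate_dataset(spec, "B", grid)
        ds_diff = synthetic_data.generate_dataset(spec, "diff", grid)
    else:
        ds_a = io_coords.pool_to_dataset(
            io_coords.read_coordinate_table(config.dataset_a_path), "A"
        )
        ds_b = io_coords.pool_to_dataset(
            io_coords.read_coordinate_table(config.dataset_b_path), "B"
        )
        ds_diff = io_coords.pool_to_dataset(
            io_coords.read_coordinate_table(config.dataset_diff_path), "A>B"
        )
    return ds_a, ds_b, ds_diff, grid


def run_cm(config: EvaluationConfig) -> AleResult:
    """Contrast-meta: full cFWE-corrected ALE on the difference-contrast dataset."""
    _, _, ds_diff, grid = load_inputs(config)
    return ale_core.cfwe_threshold(
        ds_diff, config.kernel, grid,
        cluster_forming_p=config.cluster_forming_p, fwe_p=config.fwe_p,
        n_perm=config.n_perm, seed=config.seed,
    )


def run_mc(config: EvaluationConfig) -> ContrastResult:
    """Meta-contrast: A > B permutation contrast of the two main effects."""
    ds_a, ds_b, _, grid = load_inputs(config)
    return contrast.run_mc(
        ds_a, ds_b, config.kernel, grid,
        n_perm=config.n_perm, alpha=config.alpha, k=config.k, seed=config.seed,
        mask_kind=config.mc_mask_kind, mask_p=config.cluster_forming_p,
        fwe_p=config.fwe_p, cfwe_n_perm=config.n_perm,
    )


def as_contrast_like(result: AleResult) -> SimpleNamespace:
    """Adapter presenting an AleResult with the ContrastResult attributes that
    compare_maps reads — used for self-comparison sanity checks."""
    return SimpleNamespace(
        grid=result.grid,
        significant=result.significant_mask,
        p_perm=result.p_uncorrected,
        z=result.z,
    )


@dataclass(frozen=True)
class EvaluationResult:
    cm: AleResult
    mc: ContrastResult
    report: ComparisonReport
    manifest: dict


def run_evaluation(config: EvaluationConfig) -> EvaluationResult:
    """Run CM, MC, and the comparison; optionally write maps, report, manifest.

    Any stage failure is re-raised annotated with the stage name; outputs
    written before the failure are retained.
    """
    timings: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 — annotate and re-raise
            raise RuntimeError(f"evaluation stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s finished in %.2f s", name, timings[name])
        return out

    ds_a, ds_b, ds_diff, grid = _stage("load_inputs", lambda: load_inputs(config))
    cm = _stage("cm", lambda: ale_core.cfwe_threshold(
        ds_diff, config.kernel, grid,
        cluster_forming_p=config.cluster_forming_p, fwe_p=config.fwe_p,
        n_perm=config.n_perm, seed=config.seed,
    ))
    if outdir:
        _write_cm(cm, grid, outdir)
    mc = _stage("mc", lambda: contrast.run_mc(
        ds_a, ds_b, config.kernel, grid,
        n_perm=config.n_perm, alpha=config.alpha, k=config.k, seed=config.seed,
        mask_kind=config.mc_mask_kind, mask_p=config.cluster_forming_p,
        fwe_p=config.fwe_p, cfwe_n_perm=config.n_perm,
    ))
    if outdir:
        _write_mc(mc, grid, outdir)
    report = _stage("compare", lambda: compare.compare_maps(
        cm, mc, min_peak_distance_mm=config.min_peak_distance_mm,
        cm_peak_p=config.cluster_forming_p, mc_peak_alpha=config.alpha,
    ))

    manifest = {
        "software": "alecontrast",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "grid": {"shape": list(grid.shape), "voxel_sizes_mm": grid.voxel_sizes.tolist()},
        "datasets": {
            "A": {"label": ds_a.label, "n_experiments": len(ds_a)},
            "B": {"label": ds_b.label, "n_experiments": len(ds_b)},
            "diff": {"label": ds_diff.label, "n_experiments": len(ds_diff)},
        },
        "stage_wall_time_s": timings,
    }
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "peaks.tsv").write_text(report.peak_table_tsv())
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return EvaluationResult(cm=cm, mc=mc, report=report, manifest=manifest)


def _write_cm(cm: AleResult, grid: BrainGrid, outdir: Path) -> None:
    io_coords.write_map(cm.ale, grid, outdir / "cm_ale.nii")
    io_coords.write_map(cm.p_uncorrected, grid, outdir / "cm_p.nii")
    io_coords.write_map(cm.z, grid, outdir / "cm_z.nii")
    io_coords.write_map(cm.cluster_labels.astype(float), grid, outdir / "cm_clusters.nii")
    io_coords.write_map(cm.significant_mask.astype(float), grid, outdir / "cm_significant.nii")
    null = {"bin_edges_step": float(np.diff(cm.null.bin_edges[:2])[0]),
            "probabilities_nonzero": {
                int(i): float(p) for i, p in enumerate(cm.null.probabilities) if p > 0
            },
            "cluster_size_null": cm.cluster_size_null.tolist()}
    (outdir / "cm_null.json").write_text(json.dumps(null))
    sizes = cm.cluster_sizes()
    lines = ["cluster_id\tsize_voxels\tsignificant"]
    for cid, size in sorted(sizes.items()):
        lines.append(f"{cid}\t{size}\t{int(cid in cm.significant_cluster_ids)}")
    (outdir / "cm_clusters.tsv").write_text("\n".join(lines) + "\n")


def _write_mc(mc: ContrastResult, grid: BrainGrid, outdir: Path) -> None:
    io_coords.write_map(mc.ale_diff, grid, outdir / "mc_diff.nii")
    io_coords.write_map(mc.p_perm, grid, outdir / "mc_p_perm.nii")
    io_coords.write_map(mc.z, grid, outdir / "mc_z.nii")
    io_coords.write_map(mc.significant.astype(float), grid, outdir / "mc_significant.nii")
    settings = {
        "direction": mc.direction, "n_perm": mc.n_perm, "alpha": mc.alpha,
        "k": mc.k, "seed": mc.seed,
        "main_effect_mask_voxels": int(mc.main_effect_mask.sum())
        if mc.main_effect_mask is not None else None,
    }
    (outdir / "mc_settings.json").write_text(json.dumps(settings, indent=2))
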