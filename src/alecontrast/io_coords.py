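"""Coordinate tables, experiment pooling, and the voxel grid.

Activation foci are peak coordinates reported by neuroimaging experiments in
MNI millimetre space.  This module reads them from CSV (canonical format:
columns ``study, group, n, x, y, z``) or from Sleuth-style text files, pools
rows into per-study-group :class:`Experiment` objects, and wraps the analysis
mask as a :class:`BrainGrid`.

Pooling rule: multiple contrasts reported by the same participant group of one
study are merged into a single experiment (union of foci, exact duplicates
removed); distinct participant groups of one study stay separate experiments.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

log = logging.getLogger(__name__)

CSV_COLUMNS = ("study", "group", "n", "x", "y", "z")


@dataclass(frozen=True)
class Experiment:
    """One study-group's contrast: its reported foci and sample size.

    ``foci`` is an (k, 3) float array of MNI mm coordinates.  The experiment is
    the unit over which ALE aggregates; its ``n_subjects`` sets the kernel
    width.
    """

    study_id: str
    n_subjects: int
    foci: np.ndarray

    def __post_init__(self) -> None:
        foci = np.asarray(self.foci, dtype=float)
        if foci.ndim != 2 or foci.shape[1] != 3 or foci.shape[0] == 0:
            raise ValidationError(
                f"experiment {self.study_id!r}: foci must be a non-empty (k, 3) array"
            )
        if not np.all(np.isfinite(foci)):
            raise ValidationError(f"experiment {self.study_id!r}: non-finite focus coordinate")
        if int(self.n_subjects) < 1:
            raise ValidationError(f"experiment {self.study_id!r}: n_subjects must be >= 1")
        if len(np.unique(foci, axis=0)) != len(foci):
            raise ValidationError(f"experiment {self.study_id!r}: duplicate focus coordinates")
        foci.setflags(write=False)
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "n_subjects", int(self.n_subjects))

    @property
    def n_foci(self) -> int:
        return int(self.foci.shape[0])


@dataclass(frozen=True)
class CoordinateDataset:
    """A named collection of experiments for one condition or contrast."""

    label: str
    experiments: tuple[Experiment, ...]

    def __post_init__(self) -> None:
        experiments = tuple(self.experiments)
        if not experiments:
            raise ValidationError(f"dataset {self.label!r}: needs at least one experiment")
        ids = [e.study_id for e in experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"dataset {self.label!r}: duplicate study_ids after pooling")
        object.__setattr__(self, "experiments", experiments)

    def __len__(self) -> int:
        return len(self.experiments)


@dataclass(frozen=True)
class BrainGrid:
    """Voxel lattice: affine (voxel index -> mm), shape, and boolean mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValidationError("grid shape must be 3 positive integers")
        if affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if mask.shape != shape:
            raise ValidationError("mask shape does not match grid shape")
        if not mask.any():
            raise ValidationError("mask is empty (no in-mask voxel)")
        if np.any(self.voxel_sizes_of(affine) <= 0):
            raise ValidationError("voxel size must be strictly positive on each axis")
        affine.setflags(write=False)
        mask.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask", mask)

    @staticmethod
    def voxel_sizes_of(affine: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return self.voxel_sizes_of(self.affine)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """(n_mask, 3) integer voxel indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return nib.affines.apply_affine(self.affine, ijk)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices (0-based) under the inverse affine."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        ijk = nib.affines.apply_affine(np.linalg.inv(self.affine), xyz)
        return np.rint(ijk).astype(int)

    def contains_mm(self, xyz: np.ndarray) -> np.ndarray:
        """True where the nearest voxel of each mm point lies inside the mask."""
        ijk = self.mm_to_voxel(xyz)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        out = np.zeros(len(ijk), dtype=bool)
        if inside.any():
            sub = ijk[inside]
            out[inside] = self.mask[sub[:, 0], sub[:, 1], sub[:, 2]]
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

Row = tuple[str, str, int, tuple[float, float, float]]


def read_coordinate_table(path: str | Path, format: str = "csv") -> list[Row]:
    """Read a foci table; returns (study_id, group_id, n_subjects, focus) rows.

    Coordinates are taken as MNI mm; no unit conversion is performed.  Sleuth
    ``// Reference=Talairach`` headers are rejected (no TAL support).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if format == "csv":
        return _read_csv(path)
    if format == "sleuth":
        return _read_sleuth(path)
    raise ValidationError(f"unknown coordinate-table format {format!r}")


def _read_csv(path: Path) -> list[Row]:
    try:
        df = pd.read_csv(path, dtype={"study": str, "group": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    rows: list[Row] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            n = int(rec.n)
            xyz = (float(rec.x), float(rec.y), float(rec.z))
        except (TypeError, ValueError):
            raise ParseError(f"{path}: malformed row at line {line_no}") from None
        if n < 1:
            raise ValidationError(f"{path}: non-positive n at line {line_no}")
        if not all(np.isfinite(xyz)):
            raise ParseError(f"{path}: non-finite coordinate at line {line_no}")
        rows.append((str(rec.study), str(rec.group), n, xyz))
    return rows


_SLEUTH_N = re.compile(r"n\s*=\s*(\d+)", re.IGNORECASE)


def _read_sleuth(path: Path) -> list[Row]:
    """Parse the Sleuth text convention: ``// Study: n=NN`` header lines
    followed by one whitespace-separated x y z triple per line."""
    rows: list[Row] = []
    study: str | None = None
    n_subjects: int | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                study, n_subjects = None, None
                continue
            if line.startswith("//"):
                body = line[2:].strip()
                if not body:
                    continue
                if body.lower().startswith("reference"):
                    if "talairach" in body.lower() or re.search(r"\btal\b", body.lower()):
                        raise ValidationError(
                            f"{path}: Talairach coordinates are not supported; "
                            "convert to MNI before import"
                        )
                    continue
                m = _SLEUTH_N.search(body)
                if m:
                    n_subjects = int(m.group(1))
                    if n_subjects < 1:
                        raise ValidationError(f"{path}: non-positive n at line {line_no}")
                name = _SLEUTH_N.sub("", body).rstrip(":, ").strip()
                if name:
                    study = name
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}: malformed coordinate row at line {line_no}")
            if study is None or n_subjects is None:
                raise ParseError(
                    f"{path}: coordinate at line {line_no} before a '// Study: n=..' header"
                )
            try:
                xyz = tuple(float(p) for p in parts)
            except ValueError:
                raise ParseError(f"{path}: malformed coordinate row at line {line_no}") from None
            rows.append((study, "1", n_subjects, xyz))  # type: ignore[arg-type]
    if not rows:
        raise ParseError(f"{path}: no foci found")
    return rows


def write_coordinate_table(rows: Iterable[Row], path: str | Path) -> None:
    """Write rows to the canonical CSV format (inverse of ``read``)."""
    recs = [
        {"study": s, "group": g, "n": n, "x": x, "y": y, "z": z}
        for (s, g, n, (x, y, z)) in rows
    ]
    pd.DataFrame(recs, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def dataset_to_rows(dataset: CoordinateDataset) -> list[Row]:
    """Flatten a pooled dataset back to table rows (group id fixed at '1')."""
    rows: list[Row] = []
    for exp in dataset.experiments:
        for focus in exp.foci:
            rows.append((exp.study_id, "1", exp.n_subjects, tuple(focus)))
    return rows


def pool_to_dataset(rows: Sequence[Row], label: str) -> CoordinateDataset:
    """Pool table rows into one experiment per (study, group).

    Foci of pooled rows are unioned with exact duplicates removed; distinct
    groups of one study become separate experiments.  When pooled rows of one
    group disagree on n, the maximum is kept (and the conflict logged) — the
    conservative choice, as a larger n never narrows the kernel relative to
    any constituent row.
    """
    if not rows:
        raise ValidationError("pool_to_dataset: no rows")
    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for study, group, n, xyz in rows:
        key = (str(study), str(group))
        if key not in groups:
            groups[key] = {"n": [], "foci": []}
            order.append(key)
        groups[key]["n"].append(int(n))
        groups[key]["foci"].append(tuple(float(v) for v in xyz))

    n_groups_per_study: dict[str, set[str]] = {}
    for study, group in order:
        n_groups_per_study.setdefault(study, set()).add(group)

    experiments = []
    for study, group in order:
        rec = groups[(study, group)]
        ns = rec["n"]
        if len(set(ns)) > 1:
            log.warning(
                "study %r group %r: conflicting n=%s across pooled rows; keeping max=%d",
                study, group, sorted(set(ns)), max(ns),
            )
        # preserve first-seen order while dropping exact duplicates
        seen: dict[tuple, None] = dict.fromkeys(rec["foci"])
        foci = np.array(list(seen), dtype=float)
        study_id = study if len(n_groups_per_study[study]) == 1 else f"{study}/{group}"
        experiments.append(Experiment(study_id=study_id, n_subjects=max(ns), foci=foci))
    return CoordinateDataset(label=label, experiments=tuple(experiments))


def load_grid(mask_path: str | Path) -> BrainGrid:
    """Load a NIfTI-1 mask volume; in-mask voxels are the strictly positive ones."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{mask_path}: mask must be a 3-D volume, got {data.ndim}-D")
    mask = data > 0
    if not mask.any():
        raise ValidationError(f"{mask_path}: mask volume has no positive voxel")
    return BrainGrid(shape=tuple(mask.shape), affine=np.asarray(img.affine), mask=mask)


def write_map(volume: np.ndarray, grid: BrainGrid, path: str | Path) -> None:
    """Write a per-voxel scalar field as NIfTI-1; out-of-mask voxels become 0."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != grid.shape:
        raise ValidationError(
            f"write_map: volume shape {volume.shape} != grid shape {grid.shape}"
        )
    if not np.all(np.isfinite(volume[grid.mask])):
        raise ValidationError("write_map: non-finite value inside the mask")
    out = np.where(grid.mask, volume, 0.0)
    nib.save(nib.Nifti1Image(out, grid.affine), str(path))
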