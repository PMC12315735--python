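"""Synthetic coordinate datasets with known ground truth.

Real coordinate corpora for this kind of evaluation are shared on request
only, so pipeline testing runs on generated datasets that emulate their
structure: per-experiment focus lists with variable sample size, convergence
centres that may be shared or differential between conditions, Gaussian
spatial jitter around those centres, and uniformly scattered noise foci
inside the analysis mask.

Three scenario presets encode the regimes of interest:

* ``differential_only`` — condition A (and the A>B difference experiments)
  converge at a centre that condition B never hits: both the contrast-meta
  (CM) and the meta-contrast (MC) should recover it.
* ``shared_activation`` — A and B converge equally at a common centre while
  the difference experiments also converge there: CM should detect it, MC
  cannot (no difference in convergence), the mechanism that makes MC blind to
  activation-strength differences in regions recruited by both conditions.
* ``null`` — noise only; A and B are exchangeable, the premise of the MC
  permutation test.

Randomness is hierarchical: each experiment's stream is derived from
(scenario seed, condition, experiment index), so adding experiments never
perturbs earlier ones and identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io_coords import BrainGrid, CoordinateDataset, Experiment, write_coordinate_table, dataset_to_rows

_CONDITION_CODES = {"A": 1, "B": 2, "diff": 3}

#: defaults: jitter of reported peaks around a true centre, per-experiment
#: uniformly scattered noise foci, and sample-size range — magnitudes typical
#: of task-fMRI coordinate corpora.
DEFAULT_JITTER_SD_MM = 5.0
DEFAULT_NOISE_FOCI_RANGE = (2, 10)
DEFAULT_N_SUBJECTS_RANGE = (10, 40)


@dataclass(frozen=True)
class GroundTruthCentre:
    """A true convergence locus and its per-condition contribution rates."""

    centre_mm: tuple[float, float, float]
    hit_rate_a: float = 0.0
    hit_rate_b: float = 0.0
    hit_rate_diff: float = 0.0
    jitter_sd_mm: float = DEFAULT_JITTER_SD_MM

    def __post_init__(self) -> None:
        for r in (self.hit_rate_a, self.hit_rate_b, self.hit_rate_diff):
            if not 0.0 <= r <= 1.0:
                raise ValidationError("hit rates must lie in [0, 1]")
        if self.jitter_sd_mm <= 0:
            raise ValidationError("jitter_sd_mm must be positive")

    def hit_rate(self, condition: str) -> float:
        return {"A": self.hit_rate_a, "B": self.hit_rate_b, "diff": self.hit_rate_diff}[condition]


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic study collection."""

    centres: tuple[GroundTruthCentre, ...] = ()
    n_experiments_a: int = 25
    n_experiments_b: int = 25
    n_experiments_diff: int = 25
    n_subjects_range: tuple[int, int] = DEFAULT_N_SUBJECTS_RANGE
    noise_foci_range: tuple[int, int] = DEFAULT_NOISE_FOCI_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_experiments_a, self.n_experiments_b, self.n_experiments_diff) < 1:
            raise ValidationError("experiment counts must be >= 1")
        lo, hi = self.n_subjects_range
        if lo < 1 or hi < lo:
            raise ValidationError("n_subjects_range must be a non-empty positive interval")
        nlo, nhi = self.noise_foci_range
        if nlo < 0 or nhi < nlo:
            raise ValidationError("noise_foci_range must be a non-empty non-negative interval")
        object.__setattr__(self, "centres", tuple(self.centres))

    def n_experiments(self, condition: str) -> int:
        return {
            "A": self.n_experiments_a,
            "B": self.n_experiments_b,
            "diff": self.n_experiments_diff,
        }[condition]

    def replace_seed(self, seed: int) -> "ScenarioSpec":
        d = asdict(self)
        d["centres"] = self.centres
        d["seed"] = int(seed)
        return ScenarioSpec(**d)


def make_box_grid(
    shape: tuple[int, int, int] = (24, 24, 24), voxel_size_mm: float = 4.0
) -> BrainGrid:
    """Centred box mask used as the default synthetic analysis volume.

    A (24, 24, 24) grid at 4 mm spans a 96 mm cube around the origin — a
    deliberately reduced stand-in for a grey-matter mask that keeps
    permutation analyses fast while leaving room for well-separated clusters.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_size_mm
    mask = np.ones(shape, dtype=bool)
    return BrainGrid(shape=shape, affine=affine, mask=mask)


def _experiment_rng(seed: int, condition: str, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_CONDITION_CODES[condition], index))
    return np.random.default_rng(ss)


def _jittered_focus(
    centre: GroundTruthCentre, grid: BrainGrid, rng: np.random.Generator
) -> np.ndarray:
    """Centre + isotropic Gaussian jitter, resampled until inside the mask.

    Resampling (rather than projecting) avoids piling probability mass on the
    mask boundary.
    """
    c = np.asarray(centre.centre_mm, dtype=float)
    for _ in range(1000):
        focus = c + rng.normal(0.0, centre.jitter_sd_mm, size=3)
        if grid.contains_mm(focus[None, :])[0]:
            return focus
    raise ValidationError(
        f"could not place a jittered focus near {centre.centre_mm} inside the mask"
    )


def generate_dataset(spec: ScenarioSpec, condition: str, grid: BrainGrid) -> CoordinateDataset:
    """Generate one condition's dataset ('A', 'B', or 'diff').

    Per experiment: n_subjects is uniform over the configured range; each
    ground-truth centre contributes one jittered focus with the condition's
    hit rate; noise foci are drawn uniformly (without replacement) over
    in-mask voxel centres.
    """
    if condition not in _CONDITION_CODES:
        raise ValidationError(f"unknown condition {condition!r}")
    if all(c.hit_rate(condition) == 0.0 for c in spec.centres) and spec.noise_foci_range[1] == 0:
        raise ValidationError("scenario would generate empty experiments (no hits, no noise)")
    for c in spec.centres:
        if not grid.contains_mm(np.asarray(c.centre_mm)[None, :])[0]:
            raise ValidationError(f"centre {c.centre_mm} lies outside the mask")

    mask_mm = grid.voxel_to_mm(grid.mask_indices)
    n_mask = len(mask_mm)
    lo_s, hi_s = spec.n_subjects_range
    lo_f, hi_f = spec.noise_foci_range

    experiments = []
    for i in range(spec.n_experiments(condition)):
        rng = _experiment_rng(spec.seed, condition, i)
        n_subjects = int(rng.integers(lo_s, hi_s + 1))
        foci: list[np.ndarray] = []
        for centre in spec.centres:
            if rng.random() < centre.hit_rate(condition):
                foci.append(_jittered_focus(centre, grid, rng))
        n_noise = int(rng.integers(lo_f, hi_f + 1))
        if n_noise:
            picks = rng.choice(n_mask, size=min(n_noise, n_mask), replace=False)
            foci.extend(mask_mm[picks])
        if not foci:  # all hit-rate draws failed and noise draw was 0
            picks = rng.choice(n_mask, size=1, replace=False)
            foci.extend(mask_mm[picks])
        experiments.append(
            Experiment(
                study_id=f"synth_{condition}_{i:03d}",
                n_subjects=n_subjects,
                foci=np.array(foci, dtype=float),
            )
        )
    return CoordinateDataset(label=f"synthetic:{condition}", experiments=tuple(experiments))


PRESET_NAMES = ("differential_only", "shared_activation", "null")

#: default ground-truth centre for signal presets (off-origin, well inside
#: the default box mask)
_SIGNAL_CENTRE_MM = (-10.0, 6.0, 8.0)
_SIGNAL_HIT_RATE = 0.6


def preset(name: str, seed: int = 0) -> ScenarioSpec:
    """Named study conditions for the three regimes of interest."""
    if name == "differential_only":
        return ScenarioSpec(
            centres=(
                GroundTruthCentre(
                    centre_mm=_SIGNAL_CENTRE_MM,
                    hit_rate_a=_SIGNAL_HIT_RATE,
                    hit_rate_b=0.0,
                    hit_rate_diff=_SIGNAL_HIT_RATE,
                ),
            ),
            n_experiments_a=30, n_experiments_b=30, n_experiments_diff=30,
            seed=seed,
        )
    if name == "shared_activation":
        return ScenarioSpec(
            centres=(
                GroundTruthCentre(
                    centre_mm=_SIGNAL_CENTRE_MM,
                    hit_rate_a=_SIGNAL_HIT_RATE,
                    hit_rate_b=_SIGNAL_HIT_RATE,
                    hit_rate_diff=_SIGNAL_HIT_RATE,
                ),
            ),
            n_experiments_a=30, n_experiments_b=30, n_experiments_diff=30,
            seed=seed,
        )
    if name == "null":
        return ScenarioSpec(
            centres=(),
            n_experiments_a=25, n_experiments_b=25, n_experiments_diff=25,
            seed=seed,
        )
    raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def write_scenario(spec: ScenarioSpec, grid: BrainGrid, outdir: str | Path) -> dict[str, Path]:
    """Materialize a scenario as canonical CSVs plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for condition in ("A", "B", "diff"):
        ds = generate_dataset(spec, condition, grid)
        path = outdir / f"dataset_{condition}.csv"
        write_coordinate_table(dataset_to_rows(ds), path)
        paths[condition] = path
    truth = {
        "seed": spec.seed,
        "centres": [asdict(c) for c in spec.centres],
        "n_experiments": {c: spec.n_experiments(c) for c in ("A", "B", "diff")},
        "n_subjects_range": list(spec.n_subjects_range),
        "noise_foci_range": list(spec.noise_foci_range),
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = truth_path
    return paths
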