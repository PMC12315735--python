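import numpy as np
import pytest

from alecontrast import ale_core
from alecontrast.ale_core import (
    AleNull,
    KernelModel,
    ale_to_p,
    analytic_null,
    build_ma_map,
    cfwe_threshold,
    compute_ale,
    kernel_profile,
)
from alecontrast.exceptions import ValidationError
from alecontrast.io_coords import CoordinateDataset, Experiment
from alecontrast.synthetic_data import make_box_grid

from conftest import random_experiment


def brute_force_ma(experiment, kernel, grid):
    """Voxel-by-voxel max over per-focus Gaussians — independent of the
    stencil-pasting implementation path."""
    lin = grid.affine[:3, :3]
    ijk = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    voxel_mm = ijk @ lin.T + grid.affine[:3, 3]
    sigma = kernel.sigma_mm(experiment.n_subjects)
    r_mm = kernel.truncation_radius_mm(experiment.n_subjects)
    stencil, radii = kernel_profile(experiment.n_subjects, kernel, grid)
    normaliser = stencil.max()  # stencil peak corresponds to d = 0
    out = np.zeros(len(voxel_mm))
    for focus in experiment.foci:
        centre_ijk = grid.mm_to_voxel(focus)[0]
        centre_mm = grid.voxel_to_mm(centre_ijk)[0]
        d2 = np.sum((voxel_mm - centre_mm) ** 2, axis=1)
        g = np.exp(-d2 / (2 * sigma**2)) * normaliser
        g[d2 > r_mm**2] = 0.0
        # restrict to the finite stencil box around the (clipped) centre
        off = np.abs(ijk - centre_ijk)
        g[np.any(off > radii, axis=1)] = 0.0
        out = np.maximum(out, g)
    return out.reshape(grid.shape)


class TestKernelProfile:
    def test_width_decreases_with_n_and_bounded_below(self, kernel):
        widths = [kernel.fwhm_mm(n) for n in (1, 5, 20, 100, 10_000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert widths[-1] > kernel.template_fwhm_mm

    @pytest.mark.parametrize("n", [1, 7, 40])
    def test_stencil_sums_to_one(self, n, kernel, grid16):
        stencil, _ = kernel_profile(n, kernel, grid16)
        assert abs(stencil.sum() - 1.0) < 1e-6

    def test_larger_sample_denser_peak(self, kernel, grid16):
        s10, _ = kernel_profile(10, kernel, grid16)
        s40, _ = kernel_profile(40, kernel, grid16)
        assert s40.max() > s10.max()

    def test_stencil_matches_closed_form_gaussian(self, kernel, grid16):
        n = 15
        stencil, radii = kernel_profile(n, kernel, grid16)
        sigma = kernel.sigma_mm(n)
        r_mm = kernel.truncation_radius_mm(n)
        vox = grid16.voxel_sizes
        axes = [np.arange(-r, r + 1) * v for r, v in zip(radii, vox)]
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        d2 = ii**2 + jj**2 + kk**2
        expected = np.exp(-d2 / (2 * sigma**2))
        expected[d2 > r_mm**2] = 0.0
        expected /= expected.sum()
        assert np.allclose(stencil, expected, atol=1e-12)


class TestMaMaps:
    def test_single_focus_peaks_at_focus_voxel(self, kernel, grid16):
        exp = Experiment("e", 20, np.array([[0.0, 0.0, 0.0]]))
        ma = build_ma_map(exp, kernel, grid16).values
        peak_ijk = np.unravel_index(np.argmax(ma), grid16.shape)
        assert np.array_equal(peak_ijk, grid16.mm_to_voxel([0.0, 0.0, 0.0])[0])

    def test_coincident_foci_equal_single_focus(self, kernel, grid16):
        one = Experiment("e", 20, np.array([[0.0, 0.0, 0.0]]))
        # two foci mapping to the same voxel after rounding
        two = Experiment("e", 20, np.array([[0.0, 0.0, 0.0], [0.4, 0.4, 0.4]]))
        ma1 = build_ma_map(one, kernel, grid16).values
        ma2 = build_ma_map(two, kernel, grid16).values
        assert np.array_equal(ma1, ma2)

    def test_ma_equals_brute_force(self, kernel, grid16, rng):
        for trial in range(5):
            exp = random_experiment(rng, grid16, max_foci=5, study_id=f"e{trial}")
            fast = build_ma_map(exp, kernel, grid16).values
            slow = brute_force_ma(exp, kernel, grid16)
            assert np.allclose(fast, slow, atol=1e-12, rtol=0)

    def test_values_in_unit_interval(self, kernel, grid16, rng):
        exp = random_experiment(rng, grid16)
        ma = build_ma_map(exp, kernel, grid16).values
        assert ma.min() >= 0.0 and ma.max() <= 1.0


class TestComputeAle:
    def test_single_map_identity(self, kernel, grid16, rng):
        ma = build_ma_map(random_experiment(rng, grid16), kernel, grid16)
        assert np.array_equal(compute_ale([ma]), ma.values)

    def test_two_half_maps(self):
        a = np.full((2, 2, 2), 0.5)
        assert np.allclose(compute_ale([a, a]), 0.75)

    def test_matches_product_formula(self, rng):
        maps = [rng.uniform(0, 0.3, (6, 6, 6)) for _ in range(20)]
        expected = 1.0 - np.prod([1.0 - m for m in maps], axis=0)
        assert np.allclose(compute_ale(maps), expected, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            compute_ale([])

    def test_union_monotone_in_experiments(self, kernel, grid16, rng):
        maps = [
            build_ma_map(random_experiment(rng, grid16, study_id=f"e{i}"), kernel, grid16)
            for i in range(4)
        ]
        ale3 = compute_ale(maps[:3])
        ale4 = compute_ale(maps)
        assert np.all(ale4 >= ale3 - 1e-15)

    def test_experiment_order_irrelevant(self, kernel, grid16, rng):
        exps = [random_experiment(rng, grid16, study_id=f"e{i}") for i in range(5)]
        maps = [build_ma_map(e, kernel, grid16) for e in exps]
        ale_fwd = compute_ale(maps)
        ale_rev = compute_ale(maps[::-1])
        assert np.array_equal(ale_fwd, ale_rev)
        null_fwd = analytic_null(maps, grid16)
        null_rev = analytic_null(maps[::-1], grid16)
        assert np.allclose(null_fwd.probabilities, null_rev.probabilities, atol=1e-12)


def monte_carlo_null(ma_maps, grid, n_draws, rng, bin_width=1e-4):
    """Independent oracle: sample one in-mask MA value per experiment and
    combine through the union formula, discretized to the same histogram grid
    the analytic null is defined on (bin lower edges, floor deposition)."""

    def floor_bin(x):
        return np.floor(x / bin_width + 1e-9) * bin_width

    ale = np.zeros(n_draws)
    for m in ma_maps:
        vals = m.values[grid.mask]
        draw = floor_bin(rng.choice(vals, size=n_draws, replace=True))
        ale = floor_bin(1.0 - (1.0 - ale) * (1.0 - draw))
    return ale


class TestAnalyticNull:
    def test_single_experiment_base_case(self, kernel, grid16, rng):
        ma = build_ma_map(random_experiment(rng, grid16), kernel, grid16)
        null = analytic_null([ma], grid16, bin_width=1e-4)
        vals = ma.values[grid16.mask]
        idx = np.floor(vals / 1e-4 + 1e-9).astype(int)
        expected = np.bincount(idx, minlength=len(null.probabilities)) / len(vals)
        assert np.allclose(null.probabilities, expected, atol=1e-12)

    def test_probabilities_sum_to_one(self, kernel, grid16, rng):
        maps = [
            build_ma_map(random_experiment(rng, grid16, study_id=f"e{i}"), kernel, grid16)
            for i in range(8)
        ]
        null = analytic_null(maps, grid16)
        assert abs(null.probabilities.sum() - 1.0) < 1e-9
        sf = null.survival
        assert np.all(np.diff(sf) <= 1e-15)

    def test_bad_bin_width_rejected(self, kernel, grid16, rng):
        ma = build_ma_map(random_experiment(rng, grid16), kernel, grid16)
        with pytest.raises(ValidationError):
            analytic_null([ma], grid16, bin_width=0.0)

    def test_matches_monte_carlo_oracle(self, kernel, rng):
        grid = make_box_grid(shape=(10, 10, 10), voxel_size_mm=4.0)
        maps = [
            build_ma_map(random_experiment(rng, grid, max_foci=4, study_id=f"e{i}"), kernel, grid)
            for i in range(5)
        ]
        null = analytic_null(maps, grid)
        mc = monte_carlo_null(maps, grid, n_draws=50_000, rng=rng)
        ale_grid = null.bin_edges[:-1][null.probabilities > 0]
        p_analytic = null.p_values(ale_grid)
        mc_sorted = np.sort(mc)
        p_mc = 1.0 - np.searchsorted(mc_sorted, ale_grid - 5e-5, side="left") / len(mc)
        assert np.max(np.abs(p_analytic - p_mc)) <= 0.01


class TestAleToP:
    def test_zero_ale_gives_p_one_nonpositive_z(self, kernel, grid16, rng):
        ma = build_ma_map(random_experiment(rng, grid16), kernel, grid16)
        null = analytic_null([ma], grid16)
        p, z = ale_to_p(np.zeros(grid16.shape), null)
        assert np.all(p == 1.0)
        assert np.all(z <= 0.0)

    def test_p_nonincreasing_in_ale(self, kernel, grid16, rng):
        maps = [
            build_ma_map(random_experiment(rng, grid16, study_id=f"e{i}"), kernel, grid16)
            for i in range(3)
        ]
        null = analytic_null(maps, grid16)
        ale = np.sort(rng.uniform(0, 1, 1000))
        p, _ = ale_to_p(ale, null)
        assert np.all(np.diff(p) <= 1e-15)

    def test_hand_built_three_bin_histogram(self):
        null = AleNull(
            bin_edges=np.array([0.0, 0.1, 0.2, 0.3]),
            probabilities=np.array([0.9, 0.09, 0.01]),
        )
        p, _ = ale_to_p(np.array([0.25]), null)
        assert p[0] == pytest.approx(0.01)
        p_mid, _ = ale_to_p(np.array([0.15]), null)
        assert p_mid[0] == pytest.approx(0.10)


class TestCfwe:
    def test_rejects_small_n_perm(self, kernel, grid16, rng):
        ds = CoordinateDataset("d", (random_experiment(rng, grid16),))
        with pytest.raises(ValidationError):
            cfwe_threshold(ds, kernel, grid16, n_perm=50)

    def test_strong_signal_cluster_significant(self, kernel, grid24, rng):
        centre = np.array([-10.0, 6.0, 8.0])
        exps = []
        for i in range(25):
            foci = [centre + rng.uniform(-5, 5, 3)]
            picks = rng.choice(grid24.n_mask, size=3, replace=False)
            foci.extend(grid24.voxel_to_mm(grid24.mask_indices[picks]))
            exps.append(Experiment(f"e{i}", int(rng.integers(10, 41)), np.array(foci)))
        ds = CoordinateDataset("strong", tuple(exps))
        res = cfwe_threshold(ds, kernel, grid24, n_perm=1000, seed=11)
        assert res.significant_cluster_ids
        sig_mm = grid24.voxel_to_mm(np.argwhere(res.significant_mask))
        assert np.linalg.norm(sig_mm - centre, axis=1).min() <= 10.0

    def test_null_entries_nonnegative_ints(self, kernel, grid16, rng):
        ds = CoordinateDataset(
            "d", tuple(random_experiment(rng, grid16, study_id=f"e{i}") for i in range(5))
        )
        res = cfwe_threshold(ds, kernel, grid16, n_perm=100, seed=1)
        assert res.cluster_size_null.dtype.kind == "i"
        assert np.all(res.cluster_size_null >= 0)

    def test_fixed_seed_reproducible(self, kernel, grid16, rng):
        ds = CoordinateDataset(
            "d", tuple(random_experiment(rng, grid16, study_id=f"e{i}") for i in range(5))
        )
        r1 = cfwe_threshold(ds, kernel, grid16, n_perm=100, seed=7)
        r2 = cfwe_threshold(ds, kernel, grid16, n_perm=100, seed=7)
        assert np.array_equal(r1.ale, r2.ale)
        assert np.array_equal(r1.cluster_size_null, r2.cluster_size_null)
        assert r1.significant_cluster_ids == r2.significant_cluster_ids


def test_doubling_n_increases_peak_ma(kernel, grid16):
    foci = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
    lo = build_ma_map(Experiment("e", 12, foci), kernel, grid16).values
    hi = build_ma_map(Experiment("e", 24, foci), kernel, grid16).values
    for focus in foci:
        i, j, k = grid16.mm_to_voxel(focus)[0]
        assert hi[i, j, k] > lo[i, j, k]
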