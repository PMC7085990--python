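"""Basis-function parametric imaging and voxel-wise Patlak."""

import numpy as np
import pytest
from scipy.optimize import nnls

from petkin.core import (
    ConfigurationError,
    FrameConvolver,
    InputFunction,
    IRREVERSIBLE_2TC,
    KineticsError,
)
from petkin.fitting import fit_tac
from petkin.parametric import (
    BasisSet,
    DynamicImage,
    default_theta_grid,
    extract_voi_values,
    fit_parametric,
    fit_voxel_basis,
    make_basis,
    patlak_voxelwise,
)
from petkin.patlak import patlak_fit
from petkin.synth import LIVER_LABEL


class TestMakeBasis:
    def test_grid_validation(self, cp, schedule):
        with pytest.raises(ConfigurationError):
            make_basis(cp, schedule, thetas=np.array([]))
        with pytest.raises(ConfigurationError):
            make_basis(cp, schedule, thetas=np.array([0.5, 0.1]))

    def test_large_theta_quasi_steady_limit(self, cp, schedule):
        # for fast kernels the convolution tracks Cp/theta
        theta = 50.0
        col = FrameConvolver(cp, schedule).favg(theta)
        cp_avg = cp.frame_averages(schedule)
        late = slice(12, None)  # smooth part of the curve
        np.testing.assert_allclose(col[late], cp_avg[late] / theta, rtol=0.01)

    def test_small_theta_tracks_running_integral(self, cp, schedule):
        basis = make_basis(cp, schedule, thetas=np.array([0.006, 0.1]))
        early = slice(0, 8)  # t << 1/theta_min
        np.testing.assert_allclose(
            basis.conv[early, 0], basis.int_avg[early], rtol=0.01
        )

    def test_zero_input_gives_zero_columns(self, schedule):
        f = InputFunction([0.0, 45.0], [0.0, 0.0])
        basis = make_basis(f, schedule, thetas=np.array([0.1, 1.0]))
        assert np.all(basis.conv == 0.0)
        assert np.all(basis.int_avg == 0.0)


class TestFitVoxelBasis:
    def _basis(self, cp, schedule):
        return make_basis(cp, schedule, thetas=default_theta_grid(32))

    def test_exact_recovery_for_theta_on_grid(self, cp, schedule):
        basis = self._basis(cp, schedule)
        k = 17
        vb, alpha, beta = 0.08, 0.02, 0.3
        voxel = vb * basis.blood_avg + alpha * basis.int_avg + beta * basis.conv[:, k]
        params, rss = fit_voxel_basis(voxel, basis)
        theta = basis.thetas[k]
        assert rss < 1e-18
        assert params.vb == pytest.approx(vb, rel=1e-8)
        assert params.K1 == pytest.approx(alpha + beta, rel=1e-8)
        assert params.ki == pytest.approx(alpha, rel=1e-6)
        assert params.k2 + params.k3 == pytest.approx(theta, rel=1e-8)

    def test_pure_trapping_limit(self, cp, schedule):
        basis = self._basis(cp, schedule)
        voxel = 0.05 * basis.blood_avg + 0.04 * basis.int_avg  # beta = 0: k2 = 0
        params, rss = fit_voxel_basis(voxel, basis)
        assert rss < 1e-18
        assert params.k2 == pytest.approx(0.0, abs=1e-10)
        assert params.ki == pytest.approx(params.K1, rel=1e-9)
        assert params.K1 == pytest.approx(0.04, rel=1e-8)

    def test_all_zero_voxel_yields_zero_parameters(self, cp, schedule):
        basis = self._basis(cp, schedule)
        params, rss = fit_voxel_basis(np.zeros(schedule.n_frames), basis)
        assert params.K1 == 0 and params.vb == 0
        assert rss == 0.0

    def test_selected_theta_minimises_rss_against_scipy_nnls(self, cp, schedule):
        # independent oracle: scipy's active-set NNLS per theta column
        basis = self._basis(cp, schedule)
        rng = np.random.default_rng(3)
        voxel = (
            0.06 * basis.blood_avg
            + 0.02 * basis.int_avg
            + 0.25 * basis.conv[:, 9]
            + rng.normal(0, 0.5, schedule.n_frames)
        )
        _, rss = fit_voxel_basis(voxel, basis)
        oracle = min(
            np.sum(
                (voxel - np.column_stack(
                    [basis.blood_avg, basis.int_avg, basis.conv[:, k]]
                ) @ nnls(np.column_stack(
                    [basis.blood_avg, basis.int_avg, basis.conv[:, k]]
                ), voxel)[0]) ** 2
            )
            for k in range(basis.thetas.size)
        )
        assert rss == pytest.approx(oracle, rel=1e-8, abs=1e-12)


class TestParametricMaps:
    def test_noise_free_phantom_recovers_lesion_ki(self, small_phantom):
        ph = small_phantom
        maps = fit_parametric(ph.dynamic, ph.input_function, vb_correction=True)
        for lab in ph.lesion_labels:
            m = ph.labels == lab
            truth = ph.truth[lab].ki
            assert np.median(maps["Ki2TC"][m]) == pytest.approx(truth, rel=0.03)

    def test_maps_respect_physical_bounds(self, small_phantom):
        ph = small_phantom
        maps = fit_parametric(ph.dynamic, ph.input_function)
        assert np.all(maps["Ki2TC"] <= maps["K1"] + 1e-12)
        assert np.all((maps["Vb"] >= 0) & (maps["Vb"] < 1))

    def test_deterministic_given_same_inputs(self, small_phantom):
        ph = small_phantom
        a = fit_parametric(ph.dynamic, ph.input_function)
        b = fit_parametric(ph.dynamic, ph.input_function)
        np.testing.assert_array_equal(a["Ki2TC"], b["Ki2TC"])
        np.testing.assert_array_equal(a["K1"], b["K1"])

    def test_voi_mean_parametric_ki_matches_nlls_of_voi_tac(self, small_phantom):
        ph = small_phantom
        maps = fit_parametric(ph.dynamic, ph.input_function)
        basis_ki, nlls_ki = [], []
        for lab in ph.lesion_labels:
            basis_ki.append(maps["Ki2TC"][ph.labels == lab].mean())
            tac = ph.dynamic.voi_tac(ph.labels, lab)
            nlls_ki.append(fit_tac(tac, ph.input_function, IRREVERSIBLE_2TC).params.ki)
        r = np.corrcoef(basis_ki, nlls_ki)[0, 1]
        assert r**2 > 0.99


class TestPatlakVoxelwise:
    def test_uniform_image_reproduces_voi_patlak(self, cp, schedule, lesion_params):
        from petkin.core import model_tac

        tac = model_tac(lesion_params, IRREVERSIBLE_2TC, cp, schedule)
        data = np.tile(tac.values, (4, 4, 2, 1))
        dyn = DynamicImage(data, schedule)
        maps = patlak_voxelwise(dyn, cp, t_star=15.0)
        ref = patlak_fit(tac, cp, t_star=15.0)
        got = maps["KiPatlak"][maps.mask]
        assert np.allclose(got, ref.ki, rtol=1e-10)
        assert np.allclose(maps["Ve"][maps.mask], ref.ve, rtol=1e-10)

    def test_lesion_mean_matches_voi_patlak(self, small_phantom):
        ph = small_phantom
        maps = patlak_voxelwise(ph.dynamic, ph.input_function, t_star=15.0)
        for lab in ph.lesion_labels:
            m = ph.labels == lab
            voi = patlak_fit(ph.dynamic.voi_tac(ph.labels, lab), ph.input_function, 15.0)
            assert maps["KiPatlak"][m].mean() == pytest.approx(voi.ki, rel=0.03)

    def test_reversible_liver_patlak_below_basis_ki(self, small_phantom):
        # the liver region has k4 > 0: Patlak underestimates its Ki
        ph = small_phantom
        m2 = fit_parametric(ph.dynamic, ph.input_function)
        mp = patlak_voxelwise(ph.dynamic, ph.input_function, t_star=15.0)
        liver = ph.labels == LIVER_LABEL
        assert mp["KiPatlak"][liver].mean() < m2["Ki2TC"][liver].mean()


class TestExtractVoiValues:
    def _maps(self, small_phantom):
        return fit_parametric(small_phantom.dynamic, small_phantom.input_function)

    def test_single_voxel_label_returns_that_voxel(self, small_phantom):
        maps = self._maps(small_phantom)
        labels = np.zeros(small_phantom.labels.shape, dtype=int)
        labels[10, 10, 8] = 1
        df = extract_voi_values(maps, labels)
        row = df[(df["label"] == 1) & (df["map"] == "K1")].iloc[0]
        assert row["mean"] == maps["K1"][10, 10, 8]
        assert row["n_voxels"] == 1

    def test_partition_recovers_global_mean(self, small_phantom):
        maps = self._maps(small_phantom)
        labels = np.ones(small_phantom.labels.shape, dtype=int)
        labels[:16] = 2  # two disjoint labels covering everything
        df = extract_voi_values(maps, labels).set_index(["label", "map"])
        n1 = df.loc[(1, "K1"), "n_voxels"]
        n2 = df.loc[(2, "K1"), "n_voxels"]
        combined = (df.loc[(1, "K1"), "mean"] * n1 + df.loc[(2, "K1"), "mean"] * n2) / (n1 + n2)
        assert combined == pytest.approx(maps["K1"].mean(), rel=1e-12)

    def test_empty_label_warns_and_yields_nan(self, small_phantom):
        maps = self._maps(small_phantom)
        labels = np.zeros(small_phantom.labels.shape, dtype=int)
        labels[0, 0, 0] = 1
        with pytest.warns(UserWarning):
            df = extract_voi_values(maps, labels, label_ids=[1, 99])
        missing = df[df["label"] == 99]
        assert missing["n_voxels"].eq(0).all()
        assert missing["mean"].isna().all()

    def test_geometry_mismatch_raises(self, small_phantom):
        maps = self._maps(small_phantom)
        with pytest.raises(KineticsError):
            extract_voi_values(maps, np.zeros((2, 2, 2), dtype=int))
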