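import numpy as np
import pytest
from scipy import stats

from collarch.simgen import (
    FibreFieldParams,
    FibrilFieldParams,
    FibrilPlacementError,
    GroupRecipe,
    SLSParams,
    default_group_recipes,
    gen_fibre_image,
    gen_fibril_mask,
    gen_group_dataset,
    gen_sls_trace,
    sample_axial_von_mises,
)


class TestFibreFieldParams:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            FibreFieldParams(kappa=float("nan")).validate()

    def test_rejects_negative_kappa(self):
        with pytest.raises(ValueError, match="kappa"):
            FibreFieldParams(kappa=-1.0).validate()

    def test_rejects_small_image(self):
        with pytest.raises(ValueError, match="image_size"):
            FibreFieldParams(image_size=32).validate()

    def test_rejects_zero_wavelength(self):
        with pytest.raises(ValueError):
            FibreFieldParams(undulation_wavelength_px=0.0).validate()


class TestGenFibreImage:
    def test_concentration_limit(self):
        params = FibreFieldParams(
            image_size=64, n_fibres=200, mean_angle_deg=30.0, kappa=1e6, seed=1
        )
        _, truth = gen_fibre_image(params)
        assert np.all(np.abs(np.asarray(truth.angles_deg) - 30.0) < 0.5)

    def test_determinism(self):
        params = FibreFieldParams(image_size=64, seed=9)
        img1, t1 = gen_fibre_image(params)
        img2, t2 = gen_fibre_image(params)
        assert np.array_equal(img1, img2)
        assert t1.angles_deg == t2.angles_deg

    def test_kappa_zero_uniform(self):
        params = FibreFieldParams(image_size=64, n_fibres=2000, kappa=0.0, seed=3)
        _, truth = gen_fibre_image(params)
        angles = np.asarray(truth.angles_deg)
        res = stats.kstest(angles, stats.uniform(loc=-90, scale=180).cdf)
        assert res.pvalue > 0.01

    def test_image_shape_and_dtype(self):
        img, _ = gen_fibre_image(FibreFieldParams(image_size=64, seed=0))
        assert img.shape == (64, 64)
        assert img.dtype == np.uint16

    def test_truth_conservation(self):
        params = FibreFieldParams(image_size=64, n_fibres=17, seed=0)
        _, truth = gen_fibre_image(params)
        assert len(truth.angles_deg) == 17

    def test_axial_doubling_recovers_mean(self):
        # doubling angles mod 360 and taking the circular mean gives 2*mu
        for kappa in (4.0, 10.0):
            rng = np.random.default_rng(0)
            angles = sample_axial_von_mises(rng, 20.0, kappa, 4000)
            doubled = np.deg2rad(2.0 * angles)
            mean2 = np.rad2deg(
                np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
            )
            assert abs(mean2 - 40.0) < 2.0


class TestGenGroupDataset:
    def test_counts(self):
        recipes = [
            GroupRecipe(lab, FibreFieldParams(image_size=64), 8)
            for lab in ("a", "b", "c", "d")
        ]
        images, labels, truths = gen_group_dataset(recipes, master_seed=0)
        assert len(images) == 32
        assert len(labels) == 32
        assert len(truths) == 32

    def test_default_recipes_kappa_monotone(self):
        recipes = default_group_recipes()
        kappas = [r.params.kappa for r in recipes]
        assert all(a < b for a, b in zip(kappas, kappas[1:]))

    def test_duplicate_labels_rejected(self):
        r = GroupRecipe("a", FibreFieldParams(image_size=64))
        with pytest.raises(ValueError, match="duplicate"):
            gen_group_dataset([r, r], 0)

    def test_needs_two_recipes(self):
        with pytest.raises(ValueError, match="at least 2"):
            gen_group_dataset([GroupRecipe("a", FibreFieldParams(image_size=64))], 0)

    def test_resultant_length_increases_with_kappa(self):
        recipes = [
            GroupRecipe(
                f"k{k}",
                FibreFieldParams(image_size=64, n_fibres=800, kappa=k),
                n_images=1,
            )
            for k in (0.5, 1.0, 2.0, 4.0)
        ]
        _, _, truths = gen_group_dataset(recipes, master_seed=5)
        lengths = []
        for truth in truths:
            doubled = np.deg2rad(2.0 * np.asarray(truth.angles_deg))
            lengths.append(
                np.hypot(np.sin(doubled).mean(), np.cos(doubled).mean())
            )
        assert all(a < b for a, b in zip(lengths, lengths[1:]))

    def test_master_seed_changes_output(self):
        recipes = [
            GroupRecipe("a", FibreFieldParams(image_size=64), 1),
            GroupRecipe("b", FibreFieldParams(image_size=64), 1),
        ]
        img1, _, _ = gen_group_dataset(recipes, 0)
        img2, _, _ = gen_group_dataset(recipes, 1)
        assert any(not np.array_equal(a, b) for a, b in zip(img1, img2))


class TestGenFibrilMask:
    def test_single_disc(self):
        params = FibrilFieldParams(
            image_size=128,
            n_fibrils=1,
            diameter_median_nm=40.0,
            diameter_log_sd=0.0,
            axial_ratio_range=(1.0, 1.0),
            pixel_size_nm=1.0,
            seed=0,
        )
        mask, minors = gen_fibril_mask(params)
        assert minors.shape == (1,)
        assert abs(minors[0] - 40.0) < 1e-9
        # rendered extent close to 40 px
        rows = np.flatnonzero(mask.any(axis=1))
        assert abs((rows[-1] - rows[0] + 1) - 40) <= 2

    def test_median_recovery(self):
        params = FibrilFieldParams(
            image_size=2048, n_fibrils=500, diameter_median_nm=36.3, seed=2
        )
        _, minors = gen_fibril_mask(params)
        assert len(minors) == 500
        assert abs(np.median(minors) - 36.3) / 36.3 < 0.05

    def test_min_gap_respected(self):
        from scipy import ndimage

        params = FibrilFieldParams(
            image_size=512, n_fibrils=40, min_gap_px=2.0, seed=1
        )
        mask, _ = gen_fibril_mask(params)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 40  # no two fibrils merged
        # dilating by the gap must not merge components either
        grown = ndimage.binary_dilation(mask, iterations=1)
        _, n_grown = ndimage.label(grown, structure=np.ones((3, 3)))
        assert n_grown == 40

    def test_density_error_names_achievable_count(self):
        params = FibrilFieldParams(
            image_size=128,
            n_fibrils=2000,
            diameter_median_nm=30.0,
            seed=0,
            max_tries_per_fibril=20,
        )
        with pytest.raises(FibrilPlacementError) as err:
            gen_fibril_mask(params)
        assert err.value.achieved < 2000

    def test_determinism(self):
        params = FibrilFieldParams(image_size=384, n_fibrils=20, seed=4)
        m1, d1 = gen_fibril_mask(params)
        m2, d2 = gen_fibril_mask(params)
        assert np.array_equal(m1, m2)
        assert np.array_equal(d1, d2)


class TestGenSLSTrace:
    def test_tau_identity(self):
        p = SLSParams(E_m=30.0, eta=600.0)
        assert p.tau == 600.0 / 30.0

    def test_elastic_limit_constant_hold(self):
        p = SLSParams(E_m=1e-12, eta=1e-10, protocol="ramp_hold", ramp_rate=1.0)
        tr = gen_sls_trace(p)
        hold = tr.stress_kpa[tr.phase == "hold"]
        assert np.allclose(hold, hold[0], rtol=1e-9)
        assert tr.expected_relaxation_rate_kpa_s == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_expected_rate(self):
        # eps0=0.1, E_m=30, tau=20 -> rate = 0.1*30*(1-exp(-3))/60
        p = SLSParams(
            E_eq=50.0, E_m=30.0, eta=600.0, protocol="ramp_hold",
            ramp_rate=1.0, hold_strain=0.1, hold_duration_s=90.0,
        )
        tr = gen_sls_trace(p)
        expected = 0.1 * 30.0 * (1.0 - np.exp(-3.0)) / 60.0
        assert tr.expected_relaxation_rate_kpa_s == pytest.approx(expected, rel=1e-12)

    def test_hold_matches_closed_form_pointwise(self):
        p = SLSParams(protocol="ramp_hold", ramp_rate=1.0, sample_rate_hz=100.0)
        tr = gen_sls_trace(p)
        hold = tr.phase == "hold"
        t = tr.time_s[hold] - tr.time_s[hold][0]
        expected = p.hold_strain * (p.E_eq + p.E_m * np.exp(-t / p.tau))
        assert np.allclose(tr.stress_kpa[hold], expected, rtol=1e-3)

    def test_triangle_rate_independent_limit(self):
        p = SLSParams(protocol="triangle", eta=1e12, E_m=30.0, ramp_rate=0.02)
        tr = gen_sls_trace(p)
        load = tr.phase == "loading"
        grid = np.linspace(0, 0.95 * p.hold_strain, 50)  # interior strains only
        s_load = np.interp(grid, tr.strain[load], tr.stress_kpa[load])
        un = ~load
        order = np.argsort(tr.strain[un])
        s_unload = np.interp(grid, tr.strain[un][order], tr.stress_kpa[un][order])
        assert np.allclose(s_load, s_unload, atol=1e-6 * s_load.max())

    def test_undersampled_flag(self):
        p = SLSParams(eta=30.0, E_m=30.0, sample_rate_hz=1.0, protocol="ramp_hold")
        assert gen_sls_trace(p).undersampled  # tau = 1 s at 1 Hz

    def test_force_back_computation(self):
        p = SLSParams()
        tr = gen_sls_trace(p)
        area = np.pi * p.diameter_mm**2 / 4
        assert np.allclose(tr.force_n, tr.stress_kpa * area * 1e-3)

    def test_invalid_protocol(self):
        with pytest.raises(ValueError, match="protocol"):
            gen_sls_trace(SLSParams(protocol="sawtooth"))
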