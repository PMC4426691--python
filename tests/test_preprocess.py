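import numpy as np
import pytest

from eemfac import (
    ConcentrationDesign,
    EEMDataset,
    FitConfig,
    ScatterSpec,
    excise_scatter,
    fit,
    flag_outliers,
    ife_correct,
    normalize_total_signal,
    raman_area,
    raman_normalize,
    reverse_normalization,
    simulate_dataset,
)
from eemfac.preprocess import ife_correct_eem, preprocess_pipeline
from eemfac.synth import apply_inner_filter


def _flat_dataset(grid, n=2, value=1.0):
    return EEMDataset(intensities=np.full((n,) + grid.shape, value), grid=grid)


class TestIfeCorrect:
    def test_zero_absorbance_is_identity(self, coarse_grid):
        eem = np.random.default_rng(0).random(coarse_grid.shape)
        wl = np.arange(200.0, 801.0)
        corrected, flagged = ife_correct_eem(eem, coarse_grid, wl, np.zeros(wl.size))
        assert np.array_equal(corrected, eem)
        assert not flagged

    def test_constant_absorbance_factor(self, coarse_grid):
        # A(ex) = A(em) = 0.3 -> factor 10^0.3 everywhere.
        eem = np.ones(coarse_grid.shape)
        wl = np.arange(200.0, 801.0)
        corrected, _ = ife_correct_eem(eem, coarse_grid, wl, np.full(wl.size, 0.3))
        assert corrected[0, 0] == pytest.approx(10**0.3, rel=1e-12)
        assert 10**0.3 == pytest.approx(1.9953, abs=1e-4)

    def test_round_trip_with_generator_attenuation(self, library, coarse_grid):
        clean, _ = simulate_dataset(
            library,
            ["G2", "G6"],
            ConcentrationDesign(4, seed=3),
            grid=coarse_grid,
            with_absorbance=True,
        )
        attenuated = apply_inner_filter(clean)
        assert not np.allclose(attenuated.intensities, clean.intensities)
        restored = ife_correct(attenuated)
        assert np.allclose(
            restored.intensities, clean.intensities, rtol=1e-10, atol=1e-12
        )

    def test_uncovering_absorbance_rejected(self, coarse_grid):
        eem = np.ones(coarse_grid.shape)
        wl = np.arange(300.0, 801.0)  # misses ex 220-295
        with pytest.raises(ValueError, match="cover"):
            ife_correct_eem(eem, coarse_grid, wl, np.zeros(wl.size))

    def test_high_absorbance_flagged(self, coarse_grid):
        eem = np.ones(coarse_grid.shape)
        wl = np.arange(200.0, 801.0)
        _, flagged = ife_correct_eem(eem, coarse_grid, wl, np.full(wl.size, 1.6))
        assert flagged


class TestRamanArea:
    def test_constant_blank(self, grid):
        blank = np.ones(grid.shape)
        assert raman_area(blank, grid) == pytest.approx(45.0)

    def test_linearity(self, grid):
        blank = np.full(grid.shape, 2.0)
        assert raman_area(blank, grid) == pytest.approx(90.0)

    def test_triangular_scan(self):
        # Scan rises 0 -> 1 linearly across [381, 426]: integral = 45/2.
        # Needs the 1 nm grid so the band endpoints are grid nodes.
        from eemfac import instrument_grid

        g = instrument_grid()
        blank = np.zeros(g.shape)
        ramp = np.clip((g.em - 381.0) / 45.0, 0.0, 1.0)
        blank[:, :] = ramp[:, None]
        assert raman_area(blank, g) == pytest.approx(22.5, rel=1e-12)

    def test_missing_excitation_rejected(self, grid):
        import eemfac

        blank = np.ones(grid.shape)
        with pytest.raises(ValueError, match="absent"):
            raman_area(blank, grid, ex=352.0)

    def test_partial_band_rejected(self):
        from eemfac import WavelengthGrid

        g = WavelengthGrid(
            ex=np.arange(300.0, 401.0, 5.0), em=np.arange(300.0, 401.0, 1.0)
        )
        with pytest.raises(ValueError, match="partially"):
            raman_area(np.ones(g.shape), g)


class TestRamanNormalize:
    def test_unit_area_identity(self, coarse_grid):
        ds = _flat_dataset(coarse_grid, value=3.0)
        out = raman_normalize(ds, 1.0)
        assert np.array_equal(out.intensities, ds.intensities)

    def test_self_normalized_blank_band_integrates_to_one(self, grid):
        rng = np.random.default_rng(4)
        blank = 0.5 + rng.random(grid.shape)
        area = raman_area(blank, grid)
        assert raman_area(blank / area, grid) == pytest.approx(1.0, rel=1e-12)

    def test_instrument_scale_arithmetic(self, coarse_grid):
        ds = _flat_dataset(coarse_grid, value=110.6)
        out = raman_normalize(ds, 55.3)
        assert out.intensities[0, 0, 0] == pytest.approx(2.0)

    def test_nonpositive_area_rejected(self, coarse_grid):
        with pytest.raises(ValueError):
            raman_normalize(_flat_dataset(coarse_grid), 0.0)


class TestExciseScatter:
    def test_zero_widths_mask_only_triangle(self, coarse_grid):
        ds = _flat_dataset(coarse_grid)
        out = excise_scatter(
            ds, ScatterSpec(rayleigh1_width=0, rayleigh2_width=0, raman_width=0)
        )
        expected = coarse_grid.em[:, None] < coarse_grid.ex[None, :]
        assert np.array_equal(out.mask[0], expected)

    def test_rayleigh_band_membership(self, coarse_grid):
        ds = _flat_dataset(coarse_grid)
        out = excise_scatter(
            ds, ScatterSpec(rayleigh1_width=15, rayleigh2_width=0, raman_width=0)
        )
        j350 = np.argmin(np.abs(coarse_grid.em - 350))
        j400 = np.argmin(np.abs(coarse_grid.em - 400))
        k350 = np.argmin(np.abs(coarse_grid.ex - 350))
        assert out.mask[0, j350, k350]
        assert not out.mask[0, j400, k350]

    def test_masked_fraction_monotone_in_widths(self, coarse_grid):
        ds = _flat_dataset(coarse_grid)
        fractions = []
        for w in (0.0, 5.0, 10.0, 20.0, 40.0):
            out = excise_scatter(
                ds, ScatterSpec(rayleigh1_width=w, rayleigh2_width=w, raman_width=w / 2)
            )
            fractions.append(out.mask.mean())
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_intensities_untouched(self, coarse_grid):
        ds = _flat_dataset(coarse_grid, value=7.0)
        out = excise_scatter(ds)
        assert np.array_equal(out.intensities, ds.intensities)


class TestTotalSignalNormalization:
    def test_unit_norm_after(self, library, coarse_grid):
        ds, _ = simulate_dataset(
            library, ["G2", "G6"], ConcentrationDesign(6, seed=9), grid=coarse_grid
        )
        out, factors = normalize_total_signal(ds)
        for i in range(out.n_samples):
            assert np.linalg.norm(out.intensities[i]) == pytest.approx(1.0)
        assert np.all(factors > 0)

    def test_already_unit_norm(self, coarse_grid):
        x = np.random.default_rng(1).random((1,) + coarse_grid.shape)
        x /= np.linalg.norm(x)
        out, factors = normalize_total_signal(EEMDataset(intensities=x, grid=coarse_grid))
        assert factors[0] == pytest.approx(1.0)
        assert np.allclose(out.intensities, x)

    def test_homogeneity(self, coarse_grid):
        x = np.random.default_rng(2).random((1,) + coarse_grid.shape)
        out1, f1 = normalize_total_signal(EEMDataset(intensities=x, grid=coarse_grid))
        out10, f10 = normalize_total_signal(
            EEMDataset(intensities=10 * x, grid=coarse_grid)
        )
        assert f10[0] == pytest.approx(10 * f1[0])
        assert np.allclose(out1.intensities, out10.intensities)

    def test_scalar_multiples_identical_after(self, coarse_grid):
        x = np.random.default_rng(3).random(coarse_grid.shape)
        ds = EEMDataset(intensities=np.stack([x, 3.7 * x]), grid=coarse_grid)
        out, _ = normalize_total_signal(ds)
        assert np.allclose(out.intensities[0], out.intensities[1])

    def test_zero_sample_rejected(self, coarse_grid):
        with pytest.raises(ValueError, match="no positive signal"):
            normalize_total_signal(_flat_dataset(coarse_grid, n=1, value=0.0))


class TestReverseNormalization:
    def test_identity_factors(self):
        scores = np.arange(6.0).reshape(3, 2)
        assert np.array_equal(reverse_normalization(scores, np.ones(3)), scores)

    def test_single_factor(self):
        scores = np.ones((2, 2))
        out = reverse_normalization(scores, np.array([10.0, 1.0]))
        assert np.array_equal(out[0], [10.0, 10.0])
        assert np.array_equal(out[1], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reverse_normalization(np.ones((3, 2)), np.ones(2))

    def test_normalize_fit_reverse_round_trip(self, ds3, fast_config):
        from eemfac.compare import match_components
        from eemfac.parafac import fmax

        dataset, _ = ds3
        raw_model = fit(dataset, 3, fast_config)
        normalized, factors = normalize_total_signal(dataset)
        norm_model = fit(normalized, 3, fast_config)
        norm_model.scores = reverse_normalization(norm_model.scores, factors)
        pairing = {
            m.index_a: m.index_b
            for m in match_components(raw_model, norm_model)
            if m.index_b is not None
        }
        for fa, fb in pairing.items():
            a = fmax(raw_model)[:, fa]
            b = fmax(norm_model)[:, fb]
            assert np.allclose(a, b, rtol=1e-6)


class TestFlagOutliers:
    def test_exchangeable_samples_no_flags(self, ds3, model3):
        dataset, _ = ds3
        report = flag_outliers(dataset, model3)
        # Lognormal scores vary, but no sample was generated differently;
        # at the default 3x-mean thresholds nothing should fire.
        assert np.all(report.leverage >= 0) and np.all(report.leverage <= 1)

    def test_foreign_sample_attains_max_leverage(self, library, coarse_grid, fast_config):
        from eemfac import component_loadings

        ds, _ = simulate_dataset(
            library, ["G2", "G6"], ConcentrationDesign(12, seed=21), grid=coarse_grid
        )
        em, ex = component_loadings(library["G3"], coarse_grid)
        ds.intensities[5] = 10.0 * np.outer(em, ex)
        model = fit(ds, 2, fast_config)
        report = flag_outliers(ds, model)
        assert np.argmax(report.leverage) == 5
        assert report.outlier_flags[5] != ""

    def test_leverage_in_unit_interval(self, ds3, model3):
        dataset, _ = ds3
        report = flag_outliers(dataset, model3)
        assert report.leverage.min() >= 0.0
        assert report.leverage.max() <= 1.0


class TestPipelineOrder:
    def test_order_contract_recorded(self, library, grid):
        ds, _ = simulate_dataset(
            library,
            ["G2", "G6"],
            ConcentrationDesign(3, seed=1),
            grid=grid,
            with_absorbance=True,
        )
        blank = np.ones(grid.shape)
        out, report = preprocess_pipeline(ds, blank)
        assert report.steps == [
            "ife_correct",
            "raman_normalize",
            "excise_scatter",
            "normalize_total_signal",
        ]
        assert out.mask.any()
        assert report.raman_area == pytest.approx(45.0)

    def test_raman_requires_blank(self, library, coarse_grid):
        ds, _ = simulate_dataset(
            library, ["G2"], ConcentrationDesign(3, seed=1), grid=coarse_grid
        )
        with pytest.raises(ValueError, match="blank"):
            preprocess_pipeline(ds, None, do_ife=False)
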