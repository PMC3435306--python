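import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiforest.preprocess import (
    LabeledCohort,
    PreprocessParams,
    QCExclusionError,
    Spectrum,
    default_grid,
    estimate_baseline,
    mean_spectrum,
    normalize_tic,
    preprocess_cohort,
    qc_filter,
    resample,
    subtract_baseline,
)
from maldiforest.simulate import generate_cohort

from conftest import small_sim_config


def spec(mz, intensity, sid="s1", sample="p1", label=None):
    return Spectrum(
        mz=np.asarray(mz, float),
        intensity=np.asarray(intensity, float),
        spectrum_id=sid,
        sample_id=sample,
        label=label,
    )


class TestResample:
    def test_constant_spectrum_stays_constant(self):
        s = spec(np.linspace(1000, 2000, 50), np.full(50, 7.0))
        out = resample(s, np.linspace(1100, 1900, 33))
        assert np.all(out.intensity == 7.0)

    def test_midpoint_is_linear(self):
        s = spec([1000.0, 1002.0], [0.0, 2.0])
        out = resample(s, np.array([1000.0, 1001.0, 1002.0]))
        assert out.intensity[1] == 1.0

    def test_own_grid_is_identity(self):
        rng = np.random.default_rng(0)
        s = spec(np.arange(1000.0, 1100.0), rng.uniform(0, 5, 100))
        out = resample(s, s.mz)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_grid_outside_span_errors_with_bounds(self):
        s = spec([1000.0, 2000.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="outside spectrum span"):
            resample(s, np.array([900.0, 1500.0]))


class TestBaseline:
    def test_flat_spectrum_baseline_is_flat(self):
        s = spec(np.arange(1000.0, 1500.0), np.full(500, 3.0))
        base = estimate_baseline(s, window_da=50)
        assert np.allclose(base.intensity, 3.0)
        corrected = subtract_baseline(s, base)
        assert np.all(corrected.intensity == 0.0)

    def test_exponential_baseline_recovered_within_5pct(self):
        """Closed-form oracle: b(m) = 100 exp(-m/3000), window 200 Da."""
        mz = np.arange(1000.0, 10001.0)
        truth = 100.0 * np.exp(-mz / 3000.0)
        base = estimate_baseline(spec(mz, truth), window_da=200)
        interior = (mz >= 1100) & (mz <= 9900)
        rel = np.abs(base.intensity[interior] / truth[interior] - 1.0)
        assert rel.max() < 0.05

    def test_peak_on_exponential_baseline_corrected_within_10pct(self):
        mz = np.arange(1000.0, 10001.0)
        baseline = 100.0 * np.exp(-mz / 3000.0)
        peak = 50.0 * np.exp(-((mz - 5000.0) ** 2) / (2 * 10.0**2))
        s = spec(mz, baseline + peak)
        corrected = subtract_baseline(s, estimate_baseline(s, window_da=200))
        apex = corrected.intensity[int(np.argmax(corrected.intensity))]
        assert abs(apex - 50.0) / 50.0 < 0.10

    def test_baseline_never_exceeds_spectrum(self):
        rng = np.random.default_rng(1)
        mz = np.arange(1000.0, 3000.0)
        s = spec(mz, np.abs(rng.normal(5, 2, mz.size)))
        base = estimate_baseline(s, window_da=100)
        assert np.all(base.intensity <= s.intensity + 1e-12)

    def test_window_larger_than_span_errors(self):
        s = spec(np.arange(1000.0, 1100.0), np.ones(100))
        with pytest.raises(ValueError, match="span"):
            estimate_baseline(s, window_da=500)

    @pytest.mark.parametrize(
        "intensity,baseline,expected",
        [([5.0, 5.0], [7.0, 7.0], [0.0, 0.0]), ([10.0, 10.0], [4.0, 4.0], [6.0, 6.0])],
    )
    def test_subtraction_clamps_at_zero(self, intensity, baseline, expected):
        s = spec([1000.0, 1001.0], intensity)
        b = spec([1000.0, 1001.0], baseline)
        assert list(subtract_baseline(s, b).intensity) == expected

    def test_subtraction_grid_mismatch_errors(self):
        s = spec([1000.0, 1001.0], [1.0, 1.0])
        b = spec([1000.0, 1002.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="grid"):
            subtract_baseline(s, b)


class TestNormalizeTic:
    def test_examples(self):
        s = spec([1000.0, 1001.0], [1.0, 3.0])
        assert list(normalize_tic(s, 1.0).intensity) == [0.25, 0.75]
        s = spec([1000.0, 1001.0, 1002.0], [2.0, 2.0, 4.0])
        assert list(normalize_tic(s, 8.0).intensity) == [2.0, 2.0, 4.0]

    def test_idempotent(self):
        s = spec(np.arange(1000.0, 1010.0), np.arange(1.0, 11.0))
        once = normalize_tic(s)
        twice = normalize_tic(once)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_zero_spectrum_raises_qc_signal(self):
        s = spec([1000.0, 1001.0], [0.0, 0.0])
        with pytest.raises(QCExclusionError):
            normalize_tic(s)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=2, max_size=40),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_sum_equals_target(self, values, target):
        s = spec(1000.0 + np.arange(len(values)), values)
        out = normalize_tic(s, target)
        assert out.tic == pytest.approx(target, rel=1e-9)


class TestMeanAndQC:
    def test_mean_of_two(self):
        a = spec([1000.0, 1001.0], [0.0, 2.0], sid="a", sample="a")
        b = spec([1000.0, 1001.0], [2.0, 4.0], sid="b", sample="b")
        assert list(mean_spectrum([a, b]).intensity) == [1.0, 3.0]

    def test_mean_of_copies_is_the_spectrum(self):
        s = spec(np.arange(1000.0, 1010.0), np.arange(10.0))
        out = mean_spectrum([s, s, s])
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_qc_excludes_zero_tic_with_reason(self):
        mz = np.arange(1000.0, 1100.0)
        good = [
            spec(mz, 1.0 + np.sin(mz / 5.0) ** 2 + i * 0.01, sid=f"g{i}", sample=f"g{i}")
            for i in range(3)
        ]
        bad = spec(mz, np.zeros(100), sid="z", sample="z")
        cohort = LabeledCohort(
            spectra=good + [bad],
            labels={s.sample_id: "case" for s in good} | {"z": "control"},
        )
        kept, report = qc_filter(cohort)
        assert len(kept) == 3
        row = report[report.spectrum_id == "z"].iloc[0]
        assert bool(row.excluded) and row.reason == "tic"

    def test_qc_clean_synthetic_cohort_keeps_everything(self):
        cohort, _ = generate_cohort(small_sim_config())
        grid = default_grid((1000.0, 4000.0))
        resampled = LabeledCohort(
            [resample(s, grid) for s in cohort.spectra], dict(cohort.labels)
        )
        kept, report = qc_filter(resampled)
        assert report["excluded"].sum() == 0 and len(kept) == len(cohort)

    def test_impossible_correlation_threshold_errors(self):
        cohort, _ = generate_cohort(small_sim_config(n_cases=2, n_controls=2))
        with pytest.raises(ValueError, match="all spectra excluded"):
            qc_filter(cohort, min_corr_to_mean=1.0 + 1e-9)


class TestPipelineProperties:
    def test_noiseless_zero_baseline_preserves_peak_ratios(self):
        """With no noise and no baseline, preprocessing must keep relative
        peak heights exactly (per-spectrum scaling only)."""
        config = small_sim_config(
            noise_sd=0.0, tic_scale_sd=0.0, mz_jitter_sd=0.0, baseline_amplitude=0.0
        )
        cohort, truth = generate_cohort(config)
        result = preprocess_cohort(
            cohort, PreprocessParams(mass_range=config.mass_range)
        )
        raw = cohort.spectra[0]
        out = next(
            s for s in result.cohort.spectra if s.sample_id == raw.sample_id
        )
        centers = np.sort(truth.marker_centers + truth.background_centers)[:6]
        idx = [int(np.argmin(np.abs(raw.mz - c))) for c in centers]
        raw_ratios = raw.intensity[idx] / raw.intensity[idx[0]]
        out_ratios = out.intensity[idx] / out.intensity[idx[0]]
        np.testing.assert_allclose(out_ratios, raw_ratios, rtol=1e-9)

    def test_replicates_averaged_per_sample(self):
        config = small_sim_config(n_replicates=2)
        cohort, _ = generate_cohort(config)
        result = preprocess_cohort(
            cohort, PreprocessParams(mass_range=config.mass_range)
        )
        assert len(result.cohort) == len(cohort.sample_ids)
        assert {s.sample_id for s in result.cohort.spectra} == set(cohort.sample_ids)
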