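"""Developmental pruning-rate estimation from density time series."""

import numpy as np
import pandas as pd
import pytest

from prunenet.prunerate import (
    CANONICAL_BINS,
    DensitySeries,
    adjust_3d,
    fit_density_curve,
    load_reference_density,
    loo_rate_test,
    percent_pruned,
)
from prunenet.synthetic_data import DensityGenSpec, gen_density


def series_from(ages, densities, ids=None):
    ids = ids or [f"s{i}" for i in range(len(ages))]
    return DensitySeries(
        pd.DataFrame(
            {"sample_id": ids, "age_days": ages, "density": densities}
        )
    )


class TestCurveFitting:
    def test_linear_data_reproduces_the_line(self):
        ages = np.arange(19, 41, 2.0)
        series = series_from(ages, 4.0 - 0.1 * (ages - 19))
        curve = fit_density_curve(series)
        assert np.max(np.abs(curve(ages) - (4.0 - 0.1 * (ages - 19)))) < 1e-6

    def test_reference_data_declines_from_peak_to_endpoint(self):
        curve = fit_density_curve(load_reference_density())
        assert curve(19) > curve(30) > curve(40)

    def test_extrapolation_is_rejected(self):
        curve = fit_density_curve(load_reference_density())
        with pytest.raises(ValueError, match="outside"):
            curve(50)

    def test_few_ages_fall_back_to_linear_with_warning(self):
        series = series_from([10, 20, 30], [3.0, 2.0, 1.0])
        with pytest.warns(UserWarning, match="linear"):
            curve = fit_density_curve(series)
        assert curve(15) == pytest.approx(2.5)


class TestPercentPruned:
    def test_linear_decay_splits_evenly(self):
        ages = np.linspace(19, 39, 11)
        series = series_from(ages, 4.0 - 0.1 * (ages - 19))
        curve = fit_density_curve(series)
        pct = percent_pruned(curve, 19, 39, 2)
        assert pct == pytest.approx([25.0, 25.0], abs=0.01)

    def test_exponential_decay_front_loads_the_loss(self):
        ages = np.linspace(19, 39, 11)
        series = series_from(ages, 1.5 + 2.0 * np.exp(-0.2 * (ages - 19)))
        curve = fit_density_curve(series, mode="interpolate")
        pct = percent_pruned(curve, 19, 39, 2)
        assert pct[0] > pct[1]

    def test_reference_two_interval_rate_is_decreasing(self):
        curve = fit_density_curve(load_reference_density())
        pct = percent_pruned(curve, 19, 39, 2)
        assert pct[0] > pct[1] > 0

    def test_scale_invariance(self):
        ages = np.linspace(19, 39, 8)
        dens = 3.0 * np.exp(-0.1 * (ages - 19)) + 1.0
        c1 = fit_density_curve(series_from(ages, dens))
        c2 = fit_density_curve(series_from(ages, 7.3 * dens))
        assert percent_pruned(c1, 19, 39, 5) == pytest.approx(
            percent_pruned(c2, 19, 39, 5)
        )


class TestLeaveOneOut:
    def test_exponential_truth_yields_significant_decreasing_rate(self, rng):
        spec = DensityGenSpec(shape="exponential", noise_sd=0.2,
                              animals_per_timepoint=3)
        series = gen_density(spec, rng)
        report = loo_rate_test(series, k_intervals=2, scheme="sample")
        assert report.interval_means[0] > report.interval_means[1]
        assert report.tests[0]["p"] < 0.01

    def test_linear_truth_is_a_null_case(self, rng):
        # a linear decay splits the loss ~evenly; no front-loading signal
        # (the fold t-test itself is anti-conservative at this scale, so the
        # check is on the substantive gap, not the p-value)
        spec = DensityGenSpec(shape="linear", noise_sd=0.25,
                              animals_per_timepoint=3, end_age=39.0)
        series = gen_density(spec, rng)
        report = loo_rate_test(series, k_intervals=2, scheme="sample")
        gap = report.interval_means[0] - report.interval_means[1]
        assert abs(gap) < 8.0
        assert all(15 < m < 35 for m in report.interval_means)

    def test_timepoint_scheme_gives_one_fold_per_bin(self):
        series = load_reference_density()
        report = loo_rate_test(series, k_intervals=2, scheme="timepoint")
        assert len(CANONICAL_BINS) == 12
        assert report.fold_values.shape[0] + report.skipped_folds == 12

    def test_fold_spread_shrinks_with_more_animals(self):
        sds = []
        for animals in (3, 6, 12):
            spec = DensityGenSpec(noise_sd=0.3, animals_per_timepoint=animals)
            series = gen_density(spec, np.random.default_rng(5))
            report = loo_rate_test(series, k_intervals=2, scheme="sample")
            sds.append(report.interval_sds.mean())
        assert sds[0] > sds[2]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            loo_rate_test(load_reference_density(), scheme="bootstrap")


class TestAdjust3D:
    def test_zero_diameter_is_identity(self):
        series = load_reference_density()
        adjusted = adjust_3d(series, section_thickness=0.05, object_diameter=0.0)
        assert np.allclose(adjusted.frame["density"], series.frame["density"])

    def test_constant_diameter_preserves_percentages(self):
        series = load_reference_density()
        adjusted = adjust_3d(series, 0.05, 0.3)
        assert np.allclose(
            adjusted.frame["density"], series.frame["density"] * (0.05 / 0.35)
        )
        p0 = percent_pruned(fit_density_curve(series), 19, 39, 2)
        p1 = percent_pruned(fit_density_curve(adjusted), 19, 39, 2)
        assert p0 == pytest.approx(p1)

    def test_age_varying_diameter_changes_the_rate(self):
        series = load_reference_density()
        adjusted = adjust_3d(series, 0.05, lambda age: 0.005 * age)
        p0 = percent_pruned(fit_density_curve(series), 19, 39, 2)
        p1 = percent_pruned(fit_density_curve(adjusted), 19, 39, 2)
        assert not np.allclose(p0, p1)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            adjust_3d(load_reference_density(), 0.0, 0.1)
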