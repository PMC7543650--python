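"""Gaussian overlap geometry and the control/case classification logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from siatdcm.density_classifier import (
    GaussianDensity,
    case_sensitivity,
    classify_parameter,
    control_density,
    gaussian_nonoverlap,
    loocv_specificity,
    mean_sensitivity,
    nonoverlap_numeric,
)
from siatdcm.errors import DegenerateInputError, InsufficientDataError


class TestNonOverlap:
    def test_identical_densities_overlap_fully(self):
        d = GaussianDensity(0.3, 0.5)
        assert gaussian_nonoverlap(d, d) == 0.0

    def test_equal_variance_closed_form(self):
        # OVL of N(0,1) and N(2,1) is 2*Phi(-1)
        got = gaussian_nonoverlap(GaussianDensity(0, 1), GaussianDensity(2, 1))
        assert got == pytest.approx(1 - 2 * stats.norm.cdf(-1), abs=1e-12)
        assert got == pytest.approx(0.68269, abs=1e-5)

    @given(
        mu=st.floats(-5, 5),
        logr=st.floats(-2.4, 2.4),  # sigma ratio up to ~11:1
        seed=st.integers(0, 10),
    )
    @settings(max_examples=40, deadline=None)
    def test_closed_form_matches_quadrature(self, mu, logr, seed):
        d1 = GaussianDensity(0.0, 1.0)
        d2 = GaussianDensity(mu, float(np.exp(logr)) ** 2)
        a = gaussian_nonoverlap(d1, d2)
        b = nonoverlap_numeric(d1, d2)
        assert a == pytest.approx(b, abs=1e-6)

    def test_symmetric_in_arguments(self):
        d1 = GaussianDensity(-0.5, 0.04)
        d2 = GaussianDensity(0.3, 0.25)
        assert gaussian_nonoverlap(d1, d2) == pytest.approx(
            gaussian_nonoverlap(d2, d1), abs=1e-12
        )

    def test_strictly_increasing_in_mean_separation(self):
        vals = [
            gaussian_nonoverlap(
                GaussianDensity(0, 0.3), GaussianDensity(mu, 0.7)
            )
            for mu in np.linspace(0.1, 8, 25)
        ]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0.999  # separation limit

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            GaussianDensity(0.0, 0.0)


class TestControlDensity:
    def test_sample_moments(self):
        d = control_density([-1.0, 0.0, 1.0])
        assert d.mean == 0.0
        assert d.variance == 1.0

    def test_translation_equivariance(self):
        x = [0.1, -0.4, 0.7, 0.2]
        d0 = control_density(x)
        d1 = control_density([v + 2.5 for v in x])
        assert d1.mean == pytest.approx(d0.mean + 2.5)
        assert d1.variance == pytest.approx(d0.variance)

    def test_monte_carlo_moment_recovery(self):
        # sampling distribution of the moments at n=21
        means, sds = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            d = control_density(rng.normal(-0.3, 0.1, 21))
            means.append(d.mean)
            sds.append(np.sqrt(d.variance))
        assert np.mean(means) == pytest.approx(-0.3, abs=0.07)
        assert np.mean(sds) == pytest.approx(0.1, abs=0.05)

    def test_requires_three_and_spread(self):
        with pytest.raises(InsufficientDataError):
            control_density([0.0, 1.0])
        with pytest.raises(DegenerateInputError):
            control_density([1.0, 1.0, 1.0])


class TestSpecificitySensitivity:
    def test_homogeneous_controls_fully_specific(self):
        # near-identical controls (tiny jitter) with posterior spread on the
        # same scale: no fold is flagged as different
        rng = np.random.default_rng(0)
        x = 0.5 + 1e-3 * rng.standard_normal(10)
        assert loocv_specificity(x, np.full(10, 1e-6)) == 100.0

    def test_single_outlier_flags_one_fold(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.1, 9), [2.0]])  # 20 group SDs away
        spec = loocv_specificity(x, np.full(10, 0.001))
        assert spec == pytest.approx(100.0 * 9 / 10)

    def test_synthetic_hv_defaults_give_high_specificity(self):
        specs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(-0.07, np.sqrt(0.1**2 + 0.05), 21)
            specs.append(loocv_specificity(x, np.full(21, 0.05)))
        assert all(80.0 <= s <= 100.0 for s in specs)

    def test_reported_mean_aggregation(self):
        assert mean_sensitivity([50, 74, 89, 93]) == 77
        assert mean_sensitivity([59, 73, 96, 100]) == 82

    def test_case_identical_to_control_scores_zero(self):
        ctrl = GaussianDensity(0.0, 0.2)
        per_case, mean = case_sensitivity(ctrl, [ctrl])
        assert per_case == [0.0]
        assert mean == 0

    def test_binary_reading_thresholds(self):
        ctrl = GaussianDensity(0.0, 0.01)
        cases = [GaussianDensity(5.0, 0.01), GaussianDensity(0.01, 0.01)]
        per_case, _ = case_sensitivity(ctrl, cases, threshold=0.95, binary=True)
        assert per_case == [100.0, 0.0]

    def test_full_report_separated_groups(self):
        rng = np.random.default_rng(3)
        hv = rng.normal(-0.07, 0.1, 21)
        sc = rng.normal(-0.66, 0.1, 4)
        rep = classify_parameter(
            "F:EV->IN:SP-SS", hv, np.full(21, 0.002), sc, np.full(4, 0.002)
        )
        assert rep.mean_sensitivity > 90
        assert rep.specificity >= 80.0
        assert all(0 <= s <= 100 for s in rep.per_case_sensitivity)
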