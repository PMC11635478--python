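"""Calibration fitting, copy-number conversion, correlations, summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evpscope.quantify import (
    CalibrationModel,
    CaptureInputs,
    captured_fraction,
    compare_groups,
    counts_by_deconvolution,
    counts_by_ratio,
    fit_single_fluorophore,
    normalized_variance,
    pairwise_correlation,
    physical_length,
    plan_acquisition,
    significance_stars,
    size_proxy,
    subpopulation_summary,
)
from evpscope.simulate import MarkerModel, sample_intensity_pairs


class TestSingleFluorophoreFit:
    def test_recovers_known_gaussian(self):
        rng = np.random.default_rng(0)
        cal = fit_single_fluorophore(rng.normal(1000.0, 150.0, 5000))
        assert abs(cal.unit_mu_adu - 1000.0) / 1000.0 < 0.02
        assert abs(cal.unit_sigma_adu - 150.0) / 150.0 < 0.10
        assert cal.fit_quality > 0.9

    def test_degenerate_identical_intensities(self):
        cal = fit_single_fluorophore(np.full(200, 800.0))
        assert cal.unit_mu_adu == 800.0
        assert cal.unit_sigma_adu == 0.0

    def test_dimer_contamination_does_not_shift_peak(self):
        rng = np.random.default_rng(1)
        monomers = rng.normal(1000.0, 120.0, 4000)
        dimers = rng.normal(2000.0, 170.0, 1200)
        cal = fit_single_fluorophore(np.concatenate([monomers, dimers]))
        assert abs(cal.unit_mu_adu - 1000.0) / 1000.0 < 0.05

    def test_too_few_spots_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_single_fluorophore(np.random.default_rng(0).normal(1000, 100, 50))

    def test_peak_indistinguishable_from_zero_refused(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="indistinguishable"):
            fit_single_fluorophore(np.abs(rng.normal(0.0, 100.0, 3000)))


class TestCountsByRatio:
    def test_exact_ratios(self):
        cal = CalibrationModel(1000.0, 100.0, 500, 0.99)
        counts, _ = counts_by_ratio(np.array([5000.0]), cal)
        assert counts[0] == 5.0
        counts, _ = counts_by_ratio(np.array([1000.0, 2000.0, 3000.0]), cal)
        np.testing.assert_allclose(counts, [1.0, 2.0, 3.0])

    def test_histogram_shape_preserved(self):
        rng = np.random.default_rng(3)
        intensities = rng.normal(5000, 500, 2000)
        cal = CalibrationModel(1000.0, 100.0, 500, 0.99)
        counts, (hist, edges) = counts_by_ratio(intensities, cal)
        ihist, iedges = np.histogram(intensities, bins=len(hist))
        np.testing.assert_array_equal(np.sort(hist), np.sort(ihist))

    def test_poisson_scene_mean_recovered(self):
        rng = np.random.default_rng(4)
        n = rng.poisson(10.0, 5000)
        n = n[n > 0]
        intensities = rng.normal(n * 1000.0, np.sqrt(n) * 200.0)
        cal = CalibrationModel(1000.0, 200.0, 500, 0.99)
        counts, _ = counts_by_ratio(intensities, cal)
        true_mean = n.mean()
        assert abs(counts.mean() - true_mean) / true_mean < 0.10


class TestDeconvolution:
    CAL = CalibrationModel(1000.0, 150.0, 1000, 0.99)

    def test_single_component_identified(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(3000.0, 150.0 * np.sqrt(3), 4000)
        dist = counts_by_deconvolution(draws, self.CAL, n_max=8)
        assert dist.weights[2] >= 0.9

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(6)
        ns = rng.choice([2, 5], size=10_000)
        draws = rng.normal(ns * 1000.0, np.sqrt(ns) * 150.0)
        dist = counts_by_deconvolution(draws, self.CAL, n_max=10)
        true_w = np.zeros(10)
        true_w[1] = (ns == 2).mean()
        true_w[4] = (ns == 5).mean()
        tv = 0.5 * np.abs(dist.weights - true_w).sum()
        assert tv < 0.1
        assert abs(dist.mean_count - ns.mean()) / ns.mean() < 0.15

    def test_weights_form_a_distribution(self):
        rng = np.random.default_rng(7)
        draws = rng.normal(2500.0, 400.0, 1000)
        dist = counts_by_deconvolution(draws, self.CAL, n_max=20)
        assert abs(dist.weights.sum() - 1.0) < 1e-9
        assert (dist.weights >= 0).all()
        assert dist.mean_count >= 1.0

    def test_nnls_matches_grid_search_oracle(self):
        """Two-admissible-count fixture: NNLS equals a dense simplex scan."""
        rng = np.random.default_rng(8)
        ns = rng.choice([1, 2], size=3000, p=[0.3, 0.7])
        draws = rng.normal(ns * 1000.0, np.sqrt(ns) * 150.0)
        dist = counts_by_deconvolution(draws, self.CAL, n_max=2, ridge=0.0)

        # oracle: scan w1 on a fine grid against the same binned objective
        from scipy import stats

        mu, sig = 1000.0, 150.0
        width = mu / 4.0
        hi = draws.max() + 3.0 * sig * np.sqrt(2)
        edges = np.arange(0.0, hi + width, width)
        target, _ = np.histogram(draws, bins=edges)
        target = target / target.sum()
        cols = []
        for n in (1, 2):
            z = (edges - n * mu) / (sig * np.sqrt(n))
            cols.append(np.diff(stats.norm.cdf(z)))
        a = np.column_stack(cols)
        grid = np.linspace(0.0, 1.0, 100_001)
        resid = a @ np.vstack([grid, 1 - grid]) - target[:, None]
        best = grid[np.argmin((resid**2).sum(axis=0))]
        assert abs(dist.weights[0] - best) < 1e-3

    def test_ill_conditioned_sigma_warns(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(3000.0, 900.0, 1000)
        bad = CalibrationModel(1000.0, 900.0, 1000, 0.5)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            counts_by_deconvolution(draws, bad, n_max=10)


def _particle_table(a, b, label="sEV CFSE+CD63+", ma="COE", mb="CFSE"):
    df = pd.DataFrame({
        "label": label, "flags": "",
        f"positive_{ma}": True, f"positive_{mb}": True,
        f"intensity_{ma}": a, f"intensity_{mb}": b,
    })
    return df


class TestPairwiseCorrelation:
    def test_perfect_correlation(self):
        x = np.linspace(100, 1000, 50)
        r, table = pairwise_correlation(_particle_table(x, x), "sEV CFSE+CD63+", "COE", "CFSE")
        assert r == pytest.approx(1.0)
        assert len(table) == 50

    def test_constant_vector_reported_as_nan(self):
        x = np.linspace(100, 1000, 50)
        with pytest.warns(UserWarning, match="constant"):
            r, _ = pairwise_correlation(_particle_table(x, np.full(50, 5.0)),
                                        "sEV CFSE+CD63+", "COE", "CFSE")
        assert np.isnan(r)

    def test_copula_correlation_recovered(self):
        rng = np.random.default_rng(10)
        m = MarkerModel(800.0, 1.5)
        a, b = sample_intensity_pairs(m, m, 0.8, 2000, rng)
        r, _ = pairwise_correlation(_particle_table(a, b), "sEV CFSE+CD63+", "COE", "CFSE")
        assert abs(r - 0.8) < 0.05

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlation(_particle_table(np.ones(5), np.ones(5)),
                                 "sEV CFSE+CD63+", "COE", "CFSE")


class TestSizeProxy:
    def test_exact_square_roots(self):
        assert size_proxy(0.0) == 0.0
        np.testing.assert_allclose(size_proxy(np.array([1.0, 4.0, 9.0])), [1.0, 2.0, 3.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            size_proxy(-1.0)

    def test_linear_in_diameter_for_area_scaled_intensity(self):
        diameters = np.linspace(60.0, 110.0, 26)  # nm
        k = 0.85  # ADU per nm^2
        intensity = k * diameters**2
        proxy = size_proxy(intensity)
        slope, intercept = np.polyfit(diameters, proxy, 1)
        fitted = slope * diameters + intercept
        ss_res = ((proxy - fitted) ** 2).sum()
        ss_tot = ((proxy - proxy.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99
        assert abs(slope - np.sqrt(k)) / np.sqrt(k) < 0.02


class TestNormalizedVariance:
    def test_equal_means_give_zero(self):
        assert normalized_variance([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_example(self):
        assert normalized_variance([1.0, 2.0, 3.0]) == pytest.approx(1.0 / 6.0)

    @given(st.floats(0.1, 1000.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, scale):
        base = np.array([1.0, 2.0, 3.0, 7.0])
        assert normalized_variance(base * scale) == pytest.approx(
            normalized_variance(base), rel=1e-9)

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValueError):
            normalized_variance([0.0, 0.0])


class TestCapturedFraction:
    def test_zero_density(self):
        f = captured_fraction(CaptureInputs(0.0, 65.0, 1e8, 0.1))
        assert f == 0.0

    def test_unphysical_fixture_warns(self):
        inputs = CaptureInputs(0.37, 65.0, 1e8, 0.1)
        with pytest.warns(UserWarning, match="mass balance"):
            f = captured_fraction(inputs)
        assert f == pytest.approx(2.405)

    def test_consistent_inputs_land_in_plausible_band(self):
        """Co-generated bulk/surface numbers give fractions in the 0.12-0.7 band."""
        f = captured_fraction(CaptureInputs(0.24, 65.0, 0.8e8, 0.5))
        assert 0.12 <= f <= 0.7

    @given(st.floats(0.001, 0.3), st.floats(0.5, 4.0))
    @settings(deadline=None, max_examples=25)
    def test_linearity_identities(self, density, factor):
        base = captured_fraction(CaptureInputs(density, 65.0, 1e9, 0.1))
        scaled_density = captured_fraction(CaptureInputs(density * factor, 65.0, 1e9, 0.1))
        scaled_bulk = captured_fraction(CaptureInputs(density, 65.0, 1e9 * factor, 0.1))
        assert scaled_density == pytest.approx(base * factor, rel=1e-9)
        assert scaled_bulk == pytest.approx(base / factor, rel=1e-9)


class TestCompareGroups:
    def test_identical_samples(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9
        t, p = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_are_powered(self):
        """N(0,1) vs N(3,1), n=5: rejection rate matches the noncentral-t oracle.

        Closed-form power at alpha=0.01 (two-sided) with noncentrality
        3/sqrt(2/5) and ~8 degrees of freedom is ~0.82; the simulated rate
        must agree within binomial scatter and clear a 0.75 floor.
        """
        from scipy import stats

        ncp = 3.0 / np.sqrt(2.0 / 5.0)
        df = 8.0
        tcrit = stats.t.ppf(0.995, df)
        power = 1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        rng = np.random.default_rng(11)
        hits = sum(
            compare_groups(rng.normal(0, 1, 5), rng.normal(3, 1, 5))[1] < 0.01
            for _ in range(400)
        )
        rate = hits / 400
        assert rate >= 0.75
        assert abs(rate - power) < 3 * np.sqrt(power * (1 - power) / 400) + 0.02

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0, 3.0])

    def test_stars(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"


def test_physical_length_unit_correspondences():
    assert physical_length(30, 0.25) == pytest.approx(7.5)
    assert physical_length(50, 0.25) == pytest.approx(12.5)
    assert physical_length(0, 0.25) == 0.0


def test_plan_acquisition_field_counts():
    assert plan_acquisition(65.0, (100.0, 100.0)) == 6500
    assert plan_acquisition(1.0, (1000.0, 1000.0)) == 1
    assert plan_acquisition(0.5, (100.0, 100.0)) == 50


def test_subpopulation_summary_table():
    rng = np.random.default_rng(12)
    rows = []
    for label, n in (("sEV CFSE+CD63+", 40), ("NP CFSE-CD63+", 25)):
        from evpscope.subpopulations import POSITIVITY_OF_LABEL

        pos = POSITIVITY_OF_LABEL[label]
        for _ in range(n):
            rows.append({
                "label": label, "flags": "",
                "positive_COE": pos[0], "positive_CFSE": pos[1], "positive_CD63": pos[2],
                "intensity_COE": 500.0 * pos[0], "intensity_CFSE": 300.0 * pos[1],
                "intensity_CD63": float(rng.normal(4000, 100)) * pos[2],
            })
    df = pd.DataFrame(rows)
    cal = CalibrationModel(400.0, 80.0, 500, 0.99)
    summary = subpopulation_summary(df, cal)
    row = summary[summary["label"] == "sEV CFSE+CD63+"].iloc[0]
    assert row["n_particles"] == 40
    assert row["mean_intensity_COE"] == pytest.approx(500.0)
    assert row["mean_cd63_count"] == pytest.approx(10.0, rel=0.05)
    npr = summary[summary["label"] == "NP CFSE-CD63+"].iloc[0]
    assert np.isnan(npr["mean_intensity_COE"])  # NP class carries no membrane dye
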