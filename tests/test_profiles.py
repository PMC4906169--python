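"""Peak finding, classification, double-Gaussian fitting, diameters, stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from golgiring.profiles import (
    FWHM_FACTOR,
    AnalysisConfig,
    DoubleGaussianFit,
    Profile,
    analyze_population,
    classify_profile,
    compare_groups,
    find_profile_peaks,
    fit_double_gaussian,
    object_diameter,
)
from golgiring.synth import GolgiPopulationSpec, generate_profile_population


def gaussian(x, b, a, mu, sigma):
    return b + a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


class TestProfileValidation:
    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="16"):
            Profile(np.arange(10.0), np.zeros(10))

    def test_non_uniform_spacing_rejected(self, profile_grid):
        pos = profile_grid.copy()
        pos[5] += 1.0
        with pytest.raises(ValueError, match="uniform"):
            Profile(pos, np.zeros_like(pos))

    @given(st.integers(16, 64), st.floats(1.0, 500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_uniform_grids_accepted(self, n, step):
        p = Profile(np.arange(n) * step, np.zeros(n))
        assert p.n == n
        assert np.isclose(p.step, step)


class TestPeakFinding:
    def test_single_gaussian_one_peak_at_centre(self, profile_grid):
        p = Profile(profile_grid, gaussian(profile_grid, 10, 100, 0, 113))
        peaks = find_profile_peaks(p)
        assert peaks.n_peaks == 1
        assert abs(peaks.positions[0]) <= p.step

    def test_two_gaussians_two_peaks(self, profile_grid):
        y = (gaussian(profile_grid, 10, 100, -300, 113)
             + gaussian(profile_grid, 0, 100, 300, 113))
        peaks = find_profile_peaks(Profile(profile_grid, y))
        assert peaks.n_peaks == 2

    def test_flat_profile_no_peaks(self, profile_grid):
        peaks = find_profile_peaks(Profile(profile_grid, np.full(41, 7.0)))
        assert peaks.n_peaks == 0

    def test_classification_rule(self, profile_grid):
        flat = find_profile_peaks(Profile(profile_grid, np.full(41, 1.0)))
        one = find_profile_peaks(
            Profile(profile_grid, gaussian(profile_grid, 10, 100, 0, 113)))
        two = find_profile_peaks(Profile(
            profile_grid,
            gaussian(profile_grid, 10, 100, -300, 113)
            + gaussian(profile_grid, 0, 100, 300, 113)))
        assert classify_profile(flat) == "rejected"
        assert classify_profile(one) == "solid"
        assert classify_profile(two) == "ring"


class TestDoubleGaussianFit:
    def test_free_mode_exact_recovery(self, profile_grid):
        # noiseless two-Gaussian data: generate-then-fit oracle
        truth = dict(b=10.0, a1=100.0, a2=100.0, mu1=-300.0, mu2=300.0,
                     s1=113.0, s2=113.0)
        y = (gaussian(profile_grid, truth["b"], truth["a1"], truth["mu1"], truth["s1"])
             + gaussian(profile_grid, 0, truth["a2"], truth["mu2"], truth["s2"]))
        fit = fit_double_gaussian(Profile(profile_grid, y), mode="free")
        assert fit.converged
        est = [fit.baseline, fit.a1, fit.a2, fit.mu1, fit.mu2, fit.sigma1, fit.sigma2]
        exp = [truth[k] for k in ("b", "a1", "a2", "mu1", "mu2", "s1", "s2")]
        for e, t in zip(est, exp):
            assert abs(e - t) / abs(t) < 1e-4

    def test_fixed_mode_pins_separation_to_resolution_limit(self, profile_grid):
        y = gaussian(profile_grid, 10, 100, 0, 113)
        fit = fit_double_gaussian(Profile(profile_grid, y), mode="fixed",
                                  resolution_limit=266.0)
        assert fit.converged
        assert abs(fit.separation - 266.0) / 266.0 < 1e-6

    @pytest.mark.parametrize("mu_off", [-150.0, 0.0, 200.0])
    def test_fixed_constraint_holds_for_any_single_peak(self, profile_grid, mu_off):
        rng = np.random.default_rng(4)
        y = gaussian(profile_grid, 5, 80, mu_off, 150) + rng.normal(0, 2, 41)
        fit = fit_double_gaussian(Profile(profile_grid, y), mode="fixed")
        assert abs(fit.separation - 266.0) / 266.0 < 1e-6

    def test_all_zero_profile_zero_solution(self, profile_grid):
        fit = fit_double_gaussian(Profile(profile_grid, np.zeros(41)), mode="free")
        assert fit.converged
        assert abs(fit.baseline) < 1e-9
        assert fit.a1 < 1e-9 and fit.a2 < 1e-9

    def test_invalid_mode_rejected(self, profile_grid):
        with pytest.raises(ValueError, match="mode"):
            fit_double_gaussian(Profile(profile_grid, np.zeros(41)), mode="banana")


class TestObjectDiameter:
    def _fit(self, mu1, mu2, s1, s2, mode="free"):
        return DoubleGaussianFit(baseline=0, a1=1, a2=1, mu1=mu1, mu2=mu2,
                                 sigma1=s1, sigma2=s2, mode=mode,
                                 resolution_limit=266.0, residual_ss=0.0,
                                 converged=True)

    def test_fwhm_arithmetic(self):
        d = object_diameter(self._fit(-200, 200, 100, 100), "fwhm")
        assert np.isclose(d.diameter, 400 + 2 * FWHM_FACTOR * 100)
        assert np.isclose(d.diameter, 870.964, atol=1e-3)

    def test_fixed_mode_arithmetic(self):
        d = object_diameter(self._fit(-133, 133, 113, 113, mode="fixed"), "fwhm")
        assert np.isclose(d.diameter, 266 + 2 * FWHM_FACTOR * 113)
        assert np.isclose(d.diameter, 798.19, atol=0.01)

    def test_width_definitions_differ_by_known_amount(self):
        fit = self._fit(-150, 150, 90, 120)
        d_fwhm = object_diameter(fit, "fwhm")
        d_2s = object_diameter(fit, "two_sigma")
        assert np.isclose(d_fwhm.diameter - d_2s.diameter,
                          (FWHM_FACTOR - 2.0) * (90 + 120))

    @given(st.floats(-500, 0), st.floats(1, 500), st.floats(10, 300),
           st.floats(10, 300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_diameter_additivity_is_exact(self, mu1, sep, s1, s2):
        # invariant: diameter = separation + w1 + w2, exactly
        fit = self._fit(mu1, mu1 + sep, s1, s2)
        for wd in ("fwhm", "two_sigma"):
            d = object_diameter(fit, wd)
            assert d.diameter == d.separation + d.w1 + d.w2
            assert d.diameter > 0

    def test_refuses_non_converged_fit(self):
        fit = DoubleGaussianFit(0, 1, 1, -100, 100, 50, 50, "free", 266.0,
                                1.0, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            object_diameter(fit)


class TestPopulationAnalysis:
    def test_all_solid_population(self, imaging_clean):
        spec = GolgiPopulationSpec(n_objects=30, solid_fraction=1.0, seed=2)
        profs, _ = generate_profile_population(spec, imaging_clean)
        summary, table = analyze_population(profs)
        assert summary.fraction_solid == 1.0
        assert len(table) == 30

    def test_classification_accuracy_on_noiseless_mixture(self, imaging_clean):
        # invariant: >= 99% correct labels for resolvable rings, noise off
        spec = GolgiPopulationSpec(n_objects=100, solid_fraction=0.5, seed=6)
        profs, truth = generate_profile_population(spec, imaging_clean)
        _, table = analyze_population(profs)
        acc = (table["class"].to_numpy() == truth.table["class"].to_numpy()).mean()
        assert acc >= 0.99

    def test_ring_diameter_recovery_with_noise(self, imaging):
        # The generator renders a ring as two PSF-width Gaussians at +-D/2, so
        # the fitted separation estimates D and each fitted width approaches
        # the PSF FWHM: expected diameter = D_mean + 2 x 266 nm (the PSF
        # broadening term).  Moderate noise (SNR ~ 10); tolerance 5%.
        spec = GolgiPopulationSpec(n_objects=150, solid_fraction=0.0, seed=3)
        profs, truth = generate_profile_population(spec, imaging)
        summary, table = analyze_population(profs)
        rings = table[table["class"] == "ring"]
        expected = truth.table.true_diameter_nm.mean() + 2 * 266.0
        assert abs(rings.diameter_nm.mean() - expected) / expected < 0.05

    def test_all_rejected_population_warns(self, profile_grid, caplog):
        flat = [Profile(profile_grid, np.full(41, 5.0), source_id=str(i))
                for i in range(3)]
        with caplog.at_level("WARNING"):
            summary, _ = analyze_population(flat)
        assert summary.n_ring == summary.n_solid == 0
        assert summary.n_rejected == 3


class TestCompareGroups:
    def test_pooled_t_hand_computed_example(self):
        res = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.method == "student_pooled"
        assert np.isclose(res.statistic, -1.0)
        assert np.isclose(res.p_two_tailed, 0.3466, atol=2e-4)

    def test_self_comparison_is_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(a, a)
        assert res.statistic == 0.0
        assert res.p_two_tailed == 1.0

    def test_swapping_samples_negates_t(self):
        a, b = [1, 2, 3, 4, 8], [2, 3, 4, 5, 6]
        r1, r2 = compare_groups(a, b), compare_groups(b, a)
        assert np.isclose(r1.statistic, -r2.statistic)
        assert np.isclose(r1.p_two_tailed, r2.p_two_tailed)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups([1.0], [1.0, 2.0])

    def test_matches_closed_form_on_random_pairs(self):
        # independent oracle: textbook pooled/Welch formulas via the t CDF
        rng = np.random.default_rng(12)
        for _ in range(100):
            na, nb = rng.integers(5, 30, 2)
            a = rng.normal(0, 1 + 2 * rng.random(), na)
            b = rng.normal(rng.normal(), 1 + 2 * rng.random(), nb)
            res = compare_groups(a, b)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            if res.method == "student_pooled":
                sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
                df = na + nb - 2
            else:
                t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = 2 * sps.t.sf(abs(t), df)
            assert abs(res.statistic - t) < 1e-10
            assert abs(res.p_two_tailed - p) < 1e-10
            assert abs(res.df - df) < 1e-8
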