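"""Variance components, wsCV, ICC, MDC, normalization, ROI tables, QC."""

import numpy as np
import pandas as pd
import pytest

from aslrepro.reliability import (
    VarianceComponents,
    fit_variance_components,
    icc_map,
    mdc_map,
    normalize_global,
    qc_motion_report,
    roi_summary,
    variance_components,
    wscv_map,
)


def anova_oracle(table):
    """Brute-force two-way (subject x repeat) ANOVA by explicit summation.

    Independent of the vectorized implementation: plain Python loops over
    cells, following the textbook sums-of-squares definitions.
    """
    table = np.asarray(table, dtype=float)
    ns, nr = table.shape
    grand = sum(table[i][j] for i in range(ns) for j in range(nr)) / (ns * nr)
    row_means = [sum(table[i][j] for j in range(nr)) / nr for i in range(ns)]
    col_means = [sum(table[i][j] for i in range(ns)) / ns for j in range(nr)]
    ss_r = nr * sum((m - grand) ** 2 for m in row_means)
    ss_c = ns * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(ns) for j in range(nr))
    ss_e = ss_tot - ss_r - ss_c
    ms_r = ss_r / (ns - 1)
    ms_c = ss_c / (nr - 1)
    ms_e = ss_e / ((ns - 1) * (nr - 1))
    return {
        "bs": max(0.0, (ms_r - ms_e) / nr),
        "se": max(0.0, (ms_c - ms_e) / ns),
        "er": ms_e,
        "ss": (ss_r, ss_c, ss_e, ss_tot),
    }


class TestVarianceComponents:
    def test_hand_table_matches_oracle(self):
        table = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 3.0, 3.0]])
        vc = variance_components(table)
        ref = anova_oracle(table)
        assert vc.sigma2_bs == pytest.approx(ref["bs"], abs=1e-12)
        assert vc.sigma2_se == pytest.approx(ref["se"], abs=1e-12)
        assert vc.sigma2_er == pytest.approx(ref["er"], abs=1e-12)

    def test_degenerate_constant_table(self):
        vc = variance_components(np.full((3, 3), 5.0))
        assert vc.sigma2_bs == 0 and vc.sigma2_se == 0 and vc.sigma2_er == 0

    def test_translation_invariance(self, rng):
        table = rng.normal(10, 2, size=(5, 4))
        a = variance_components(table)
        b = variance_components(table + 123.4)
        assert a.sigma2_bs == pytest.approx(b.sigma2_bs, abs=1e-9)
        assert a.sigma2_se == pytest.approx(b.sigma2_se, abs=1e-9)
        assert a.sigma2_er == pytest.approx(b.sigma2_er, abs=1e-9)

    def test_sum_of_squares_conservation(self, rng):
        """Total SS decomposes exactly into subject + repeat + residual SS."""
        for _ in range(20):
            table = rng.normal(size=(4, 3))
            ss_r, ss_c, ss_e, ss_tot = anova_oracle(table)["ss"]
            assert ss_r + ss_c + ss_e == pytest.approx(ss_tot, abs=1e-10)

    def test_voxel_axis_broadcasting(self, rng):
        tables = rng.normal(50, 5, size=(5, 3, 7))
        vc = variance_components(tables)
        for v in range(7):
            ref = anova_oracle(tables[:, :, v])
            assert vc.sigma2_bs[v] == pytest.approx(ref["bs"], abs=1e-10)

    def test_minimum_design_size(self):
        with pytest.raises(ValueError):
            variance_components(np.ones((1, 3)))
        with pytest.raises(ValueError):
            variance_components(np.ones((3, 1)))

    def test_missing_cells_rejected(self):
        table = np.ones((3, 3))
        table[1, 2] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            variance_components(table)


class TestStackModes:
    def test_between_session_uses_run_averaged_means(self, rng):
        stack = rng.normal(60, 5, size=(5, 3, 2))
        vc = fit_variance_components(stack, "between-session")
        ref = variance_components(stack.mean(axis=2))
        assert vc.sigma2_se == pytest.approx(ref.sigma2_se, abs=1e-12)

    def test_within_session_averages_per_session_estimates(self, rng):
        stack = rng.normal(60, 5, size=(5, 3, 2))
        vc = fit_variance_components(stack, "within-session")
        per = [variance_components(stack[:, s]) for s in range(3)]
        assert vc.sigma2_er == pytest.approx(np.mean([v.sigma2_er for v in per]))

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError, match="mode"):
            fit_variance_components(rng.normal(size=(4, 3, 2)), "weekly")


def _vc(bs, se, er, mean=100.0):
    return VarianceComponents(
        sigma2_bs=np.asarray(bs, float), sigma2_se=np.asarray(se, float),
        sigma2_er=np.asarray(er, float), grand_mean=np.asarray(mean, float),
        n_subjects=5, n_repeats=3,
    )


class TestWscv:
    def test_two_point_repeats(self):
        """Two repeats 90 and 110 for every subject: within-subject SD is
        |110-90|/sqrt(2) = 14.142, so wsCV = 14.1% of the mean 100."""
        table = np.array([[90.0, 110.0], [90.0, 110.0]])
        vc = variance_components(table)
        assert wscv_map(vc) == pytest.approx(100 * 20 / np.sqrt(2) / 100, abs=1e-9)

    def test_zero_variance(self):
        assert wscv_map(_vc(4.0, 0.0, 0.0)) == 0.0

    def test_scale_invariance(self, rng):
        table = rng.normal(50, 4, size=(5, 3))
        a = wscv_map(variance_components(table))
        b = wscv_map(variance_components(table * 7.3))
        assert a == pytest.approx(b, rel=1e-10)

    def test_undefined_for_nonpositive_mean(self):
        assert np.isnan(wscv_map(_vc(1.0, 1.0, 1.0, mean=0.0)))


class TestIcc:
    def test_direct_ratio(self):
        assert icc_map(_vc(9.0, 0.5, 0.5)) == pytest.approx(0.9)

    def test_perfect_reliability(self):
        assert icc_map(_vc(3.0, 0.0, 0.0)) == 1.0

    def test_undefined_when_total_zero(self):
        assert np.isnan(icc_map(_vc(0.0, 0.0, 0.0)))

    def test_estimator_bias_shrinks_with_subjects(self, rng):
        """Consistency in the subject direction: the mean estimated ICC
        approaches the true ratio as subjects grow from 20 to 100.

        The systemic component is held at zero here: its mean square has only
        k-1 degrees of freedom regardless of subject count, so with a nonzero
        systemic effect the plug-in ratio keeps an O(var(sigma2_se)) bias that
        no amount of subjects removes; without it every bias term is O(1/n).
        """
        true_bs, true_er = 25.0, 8.0
        truth = true_bs / (true_bs + true_er)

        def mean_icc(n_subj, reps=500):
            out = []
            for _ in range(reps):
                b = rng.normal(0, np.sqrt(true_bs), size=(n_subj, 1))
                e = rng.normal(0, np.sqrt(true_er), size=(n_subj, 3))
                out.append(icc_map(variance_components(60.0 + b + e)))
            return float(np.mean(out))

        bias_small = abs(mean_icc(20) - truth)
        bias_large = abs(mean_icc(100) - truth)
        assert bias_large < bias_small


class TestMdc:
    def test_hand_value_default_form(self):
        """SD 5, n 96, t_crit 5 -> 5/sqrt(96)*5 = 2.55 ml/100g/min."""
        vc = _vc(0.0, 0.0, 25.0)
        assert mdc_map(vc, n=96, t_crit=5.0) == pytest.approx(2.5516, abs=1e-4)

    def test_printed_form_divides(self):
        vc = _vc(0.0, 0.0, 25.0)
        assert mdc_map(vc, 96, 5.0, form="printed") == pytest.approx(
            5 / np.sqrt(96) / 5, abs=1e-9
        )

    def test_zero_sd(self):
        assert mdc_map(_vc(9.0, 0.0, 0.0), 96, 5.0) == 0.0

    def test_monotone_in_n(self):
        vc = _vc(0.0, 1.0, 1.0)
        assert mdc_map(vc, 100, 5.0) <= mdc_map(vc, 10, 5.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mdc_map(_vc(1, 1, 1), 1, 5.0)
        with pytest.raises(ValueError):
            mdc_map(_vc(1, 1, 1), 96, 0.0)


class TestNormalizeGlobal:
    def test_constant_map_gives_ones(self):
        vol = np.full((4, 4, 4), 42.0)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        np.testing.assert_allclose(normalize_global(vol, mask), 1.0)

    def test_scale_invariance_and_unit_gm_mean(self, rng):
        vol = rng.uniform(20, 80, size=(5, 5, 5))
        mask = vol > 40
        a = normalize_global(vol, mask)
        b = normalize_global(vol * 3.7, mask)
        np.testing.assert_allclose(a, b)
        assert a[mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_global(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError, match="nonpositive"):
            normalize_global(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))


class TestRoiSummary:
    def test_constant_map(self):
        mask = np.ones((3, 3, 3), bool)
        out = roi_summary({"icc": np.full((3, 3, 3), 0.8)}, {"all": mask})
        assert out.loc[0, "mean"] == pytest.approx(0.8)
        assert out.loc[0, "sd"] == pytest.approx(0.0)

    def test_two_voxel_mean(self):
        vol = np.zeros((2, 2, 1))
        vol[0, 0, 0], vol[1, 1, 0] = 0.8, 0.9
        mask = vol > 0
        out = roi_summary({"icc": vol}, {"pair": mask})
        assert out.loc[0, "mean"] == pytest.approx(0.85)

    def test_disjoint_masks_recombine_by_voxel_count(self, rng):
        vol = rng.uniform(size=(6, 6, 6))
        m1 = np.zeros_like(vol, bool)
        m2 = np.zeros_like(vol, bool)
        m1[:2], m2[3:] = True, True
        whole = m1 | m2
        out = roi_summary({"v": vol}, {"a": m1, "b": m2, "w": whole})
        g = out.set_index("roi")
        combined = (
            g.loc["a", "mean"] * g.loc["a", "n_voxels"]
            + g.loc["b", "mean"] * g.loc["b", "n_voxels"]
        ) / g.loc["w", "n_voxels"]
        assert combined == pytest.approx(g.loc["w", "mean"], rel=1e-12)

    def test_undefined_voxels_excluded_and_counted(self):
        vol = np.full((2, 2, 2), 0.5)
        vol[0, 0, 0] = np.nan
        out = roi_summary({"icc": vol}, {"all": np.ones((2, 2, 2), bool)})
        assert out.loc[0, "n_undefined"] == 1
        assert out.loc[0, "mean"] == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_summary({"v": np.ones((2, 2, 2))}, {"none": np.zeros((2, 2, 2), bool)})


class TestQcMotion:
    def test_threshold_flags(self):
        df = pd.DataFrame(
            {
                "run": [1, 2, 3],
                "translation_mm": [3.1, 0.0, 0.0],
                "rotation_deg": [0.0, 0.0, 2.9],
            }
        )
        out = qc_motion_report(df)
        assert list(out["qc_pass"]) == [False, True, True]

    def test_missing_entries_rejected(self):
        df = pd.DataFrame({"translation_mm": [1.0, np.nan], "rotation_deg": [0.0, 0.0]})
        with pytest.raises(ValueError, match="missing"):
            qc_motion_report(df)


class TestGlobalFactorProperty:
    def test_normalization_removes_multiplicative_session_noise(self, rng):
        """With only a session-level global factor, wsCV on normalized data is
        (numerically) zero while wsCV on absolute data is not."""
        profile = rng.uniform(30, 90, size=40)  # spatial CBF pattern
        g = rng.normal(1.0, 0.1, size=(6, 3, 2, 1))  # subject x session x run
        stack_a = profile[None, None, None, :] * g
        stack_r = stack_a / stack_a.mean(axis=3, keepdims=True)
        wscv_a = wscv_map(fit_variance_components(stack_a, "between-session"))
        wscv_r = wscv_map(fit_variance_components(stack_r, "between-session"))
        assert np.all(wscv_r <= wscv_a + 1e-9)
        assert wscv_a.mean() > 1.0  # the global factor is visible in aCBF
        assert wscv_r.mean() == pytest.approx(0.0, abs=1e-6)
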