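import numpy as np
import pytest

from gaitcal import (GaitTensor, InputError, bland_altman, classify_cmc,
                     classify_icc, cmc, gated_correlation, icc_2k,
                     reliability_report, rmse_waveform, sem, validity_report)
from gaitcal.stats import CMC_SENTINEL


def brute_force_cmc(Y):
    """Independent loop-based evaluation of the CMC formula."""
    M, T = Y.shape
    tmean = [sum(Y[m][t] for m in range(M)) / M for t in range(T)]
    gmean = sum(sum(row) for row in Y) / (M * T)
    num = sum((Y[m][t] - tmean[t]) ** 2
              for m in range(M) for t in range(T)) / (T * (M - 1))
    den = sum((Y[m][t] - gmean) ** 2
              for m in range(M) for t in range(T)) / (M * T - 1)
    return 1.0 - num / den


def brute_force_icc2k(X):
    """Two-way ANOVA mean squares evaluated with explicit loops."""
    n, k = X.shape
    gm = sum(sum(r) for r in X) / (n * k)
    rm = [sum(r) / k for r in X]
    cm = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((v - gm) ** 2 for v in rm)
    ssc = n * sum((v - gm) ** 2 for v in cm)
    sst = sum((X[i][j] - gm) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestRmse:
    def test_identical(self, rng):
        a = rng.normal(size=101)
        assert rmse_waveform(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = rng.normal(size=101)
        assert rmse_waveform(a, a + 3.0) == pytest.approx(3.0)

    def test_brute_force(self, rng):
        a, b = rng.normal(size=(2, 101))
        expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 101)
        assert rmse_waveform(a, b) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            rmse_waveform(np.zeros(5), np.zeros(6))


class TestCMC:
    def test_identical_nonconstant_waveforms(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 101))
        out = cmc(np.stack([w, w]))
        assert out.value == pytest.approx(1.0)
        assert not out.is_sentinel

    def test_constant_offset_waveforms_give_sentinel(self):
        out = cmc(np.stack([np.zeros(101), np.full(101, 10.0)]))
        assert out.is_sentinel
        assert out.label == CMC_SENTINEL
        assert out.radicand < 0

    def test_integer_matrix_matches_brute_force(self):
        Y = np.array([[1, 4, 2, 8, 5],
                      [2, 5, 1, 9, 4],
                      [0, 4, 3, 7, 6]], dtype=float)
        expected = brute_force_cmc(Y)
        out = cmc(Y)
        assert out.radicand == pytest.approx(expected, rel=1e-12)
        assert out.value == pytest.approx(np.sqrt(expected), rel=1e-12)

    def test_degenerate_all_identical(self):
        out = cmc(np.full((3, 10), 2.0))
        assert out.value == 1.0
        assert out.degenerate

    def test_invariant_to_common_offset(self, rng):
        w = np.sin(np.linspace(0, 2 * np.pi, 101))
        Y = w + rng.normal(0, 0.1, size=(4, 101))
        assert cmc(Y + 17.0).value == pytest.approx(cmc(Y).value, rel=1e-9)

    def test_decreases_when_one_waveform_offset(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 101))
        base = cmc(np.stack([w, w + 0.01])).value
        shifted = cmc(np.stack([w, w + 0.5])).value
        assert shifted < base

    def test_needs_two_waveforms(self):
        with pytest.raises(InputError):
            cmc(np.zeros((1, 101)))


class TestClassifyCMC:
    @pytest.mark.parametrize("value,band", [
        (0.97, "excellent"), (0.95, "excellent"),
        (0.90, "very good"), (0.85, "very good"),
        (0.80, "good"), (0.75, "good"),
        (0.70, "moderate"), (0.60, "moderate"),
        (0.59, "poor"), (0.0, "poor"),
    ])
    def test_bands(self, value, band):
        assert classify_cmc(value) == band

    def test_sentinel_is_poor(self):
        out = cmc(np.stack([np.zeros(10), np.full(10, 5.0)]))
        assert classify_cmc(out) == "poor"


class TestGatedCorrelation:
    def test_exact_linear_gaussian_pearson(self, rng):
        x = rng.normal(size=30)
        out = gated_correlation(x, 2 * x + 1)
        assert out.method == "pearson"
        assert out.coefficient == pytest.approx(1.0)

    def test_monotone_skewed_spearman(self, rng):
        x = np.exp(3.0 * rng.normal(size=50))
        out = gated_correlation(x, x ** 3)
        assert out.method == "spearman"
        assert out.coefficient == pytest.approx(1.0)

    def test_matches_textbook_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        out = gated_correlation(x, y)
        xd, yd = x - x.mean(), y - y.mean()
        expected = np.sum(xd * yd) / np.sqrt(np.sum(xd**2) * np.sum(yd**2))
        if out.method == "pearson":
            assert out.coefficient == pytest.approx(expected, rel=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(InputError):
            gated_correlation(np.full(10, 3.0), np.arange(10.0))


class TestBlandAltman:
    def test_identical(self, rng):
        x = rng.normal(size=20)
        out = bland_altman(x, x)
        assert (out.mean_diff, out.loa_lower, out.loa_upper) == (0, 0, 0)

    def test_exact_shift(self, rng):
        x = rng.normal(size=20)
        out = bland_altman(x, x - 5.0)
        assert out.mean_diff == pytest.approx(5.0)
        assert out.loa_lower == pytest.approx(5.0)
        assert out.loa_upper == pytest.approx(5.0)

    def test_known_sd_monte_carlo(self, rng):
        sigma = 2.0
        d = rng.normal(0, sigma, 5000)
        out = bland_altman(d, np.zeros_like(d))
        assert out.loa_upper == pytest.approx(1.96 * sigma, abs=0.15)
        assert out.loa_lower == pytest.approx(-1.96 * sigma, abs=0.15)

    def test_mean_diff_bounded_by_rmse(self, rng):
        x, y = rng.normal(size=(2, 101))
        out = bland_altman(x, y)
        assert out.mean_diff ** 2 <= rmse_waveform(x, y) ** 2 + 1e-12

    def test_too_few(self):
        with pytest.raises(InputError):
            bland_altman(np.array([1.0]), np.array([2.0]))


class TestICC:
    def test_identical_columns(self):
        X = np.array([[1, 1], [2, 2], [5, 5], [9, 9]], dtype=float)
        out = icc_2k(X)
        assert out.icc == pytest.approx(1.0)

    def test_hand_computed_matrix(self):
        X = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        # MSR=40/3, MSC=2, MSE=0 -> ICC(2,k) = (40/3)/(40/3 + 2/4)
        assert icc_2k(X).icc == pytest.approx((40 / 3) / (40 / 3 + 0.5))
        assert icc_2k(X).icc == pytest.approx(brute_force_icc2k(X))

    def test_independent_columns_near_zero(self, rng):
        X = rng.normal(size=(200, 2))
        out = icc_2k(X)
        assert abs(out.icc) < 0.15

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            X = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2.0
            n, k = X.shape
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": X.ravel()})
            res = pingouin.intraclass_corr(df, targets="subject",
                                           raters="rater", ratings="score")
            mask = res["Type"].isin(["ICC2k", "ICC(A,k)"])
            row = res[mask].iloc[0]
            out = icc_2k(X)
            assert out.icc == pytest.approx(row["ICC"], abs=1e-9)
            ci_col = "CI95" if "CI95" in res.columns else "CI95%"
            # pingouin rounds the CI to 2 decimals
            assert out.ci_low == pytest.approx(row[ci_col][0], abs=5e-3)
            assert out.ci_high == pytest.approx(row[ci_col][1], abs=5e-3)

    def test_zero_between_subject_variance(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        out = icc_2k(X)
        assert out.icc == 0.0
        assert out.degenerate

    def test_missing_cells_rejected(self):
        X = np.array([[1.0, np.nan], [2, 3], [4, 5]])
        with pytest.raises(InputError):
            icc_2k(X)


class TestSEM:
    def test_arithmetic(self):
        assert sem(10.0, 0.75) == pytest.approx(5.0)
        assert sem(8.0, 0.64) == pytest.approx(4.8)

    def test_perfect_reliability(self):
        assert sem(10.0, 1.0) == 0.0

    def test_negative_icc_exceeds_sd(self):
        assert sem(10.0, -0.23) > 10.0

    def test_icc_above_one_rejected(self):
        with pytest.raises(InputError):
            sem(10.0, 1.1)


class TestClassifyICC:
    @pytest.mark.parametrize("value,band", [
        (0.93, "excellent"), (0.75, "excellent"),
        (0.45, "modest"), (0.40, "modest"),
        (0.39, "poor"), (-0.23, "poor"),
    ])
    def test_bands(self, value, band):
        assert classify_icc(value) == band


def _cohort_tensor(rng, n_subjects=5, n_trials=2, shift=0.0, noise=0.0):
    base = np.sin(np.linspace(0, 2 * np.pi, 101))[:, None] * \
        np.array([30, 8, 5, 25, 10]) + np.array([20, 2, 0, 30, -2])
    vals, subjects = [], []
    for s in range(n_subjects):
        subj_curve = base * (1.0 + rng.normal(0, 0.08, size=(1, 5))) \
            + rng.normal(0, 2.0, size=(1, 5))
        for _ in range(n_trials):
            vals.append(subj_curve + shift
                        + rng.normal(0, noise, size=(101, 5)))
            subjects.append(f"S{s}")
    return GaitTensor(np.stack(vals), subjects=subjects)


class TestReports:
    def test_validity_self_comparison(self, rng):
        ref = _cohort_tensor(rng)
        report = validity_report(ref, {"same": ref})
        for dof, per_sys in report.content["waveforms"].items():
            st = per_sys["same"]
            assert st["rmse_mean"] == pytest.approx(0.0, abs=1e-12)
            assert st["cmc_mean"] == pytest.approx(1.0)
            assert st["band"] == "excellent"
        for dof, per_param in report.content["parameters"].items():
            for param, per_sys in per_param.items():
                corr = per_sys["same"]["correlation"]
                assert corr["coefficient"] == pytest.approx(1.0)
                ba = per_sys["same"]["bland_altman"]
                assert ba["mean_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_validity_report_roundtrips_through_json(self, rng, tmp_path):
        ref = _cohort_tensor(rng)
        sys1 = GaitTensor(0.8 * ref.values - 4.0, subjects=ref.subjects)
        report = validity_report(ref, {"depth": sys1})
        path = tmp_path / "validity.json"
        report.to_json(path)
        from gaitcal import AgreementReport

        loaded = AgreementReport.from_json(path)
        assert loaded.to_dict() == report.to_dict()

    def test_reliability_identical_days(self, rng):
        day1 = _cohort_tensor(rng)
        report = reliability_report(day1, day1)
        for dof, per_param in report.content["parameters"].items():
            for param, st in per_param.items():
                entry = st["between-day"]
                assert entry["icc"]["value"] == pytest.approx(1.0)
                assert entry["sem"] == pytest.approx(0.0, abs=1e-6)
        for dof, st in report.content["waveforms"].items():
            assert st["between-day"]["cmc_mean"] == pytest.approx(1.0)
            assert st["between-day"]["rmse_mean"] == pytest.approx(0.0)

    def test_sem_grows_with_between_day_noise(self, rng):
        sems = []
        for sigma in (0.5, 2.0, 8.0):
            r = np.random.default_rng(7)
            day1 = _cohort_tensor(r, n_subjects=8)
            day2 = GaitTensor(day1.values + r.normal(0, sigma,
                                                     day1.values.shape),
                              subjects=day1.subjects)
            rep = reliability_report(day1, day2)
            sems.append(np.mean([
                rep.content["parameters"][dof]["rom"]["between-day"]["sem"]
                for dof in rep.content["parameters"]]))
        assert sems[0] < sems[1] < sems[2]

    def test_shuffled_subjects_destroy_icc(self, rng):
        day1 = _cohort_tensor(rng, n_subjects=10)
        perm = np.random.default_rng(3).permutation(10)
        subj_order = [f"S{i}" for i in range(10)]
        means = {s: day1.values[[i for i, x in enumerate(day1.subjects)
                                 if x == s]].mean(axis=0)
                 for s in subj_order}
        shuffled_vals = np.stack([means[subj_order[p]] for p in perm])
        day2 = GaitTensor(shuffled_vals, subjects=subj_order)
        rep = reliability_report(day1, day2)
        iccs = [rep.content["parameters"][dof]["maximum"]["between-day"]
                ["icc"]["value"] for dof in rep.content["parameters"]]
        # shuffling destroys agreement: no DOF retains a high positive ICC
        # (the estimator is unbounded below, so magnitudes can exceed 1)
        assert max(iccs) < 0.5

    def test_tables_have_expected_shape(self, rng):
        ref = _cohort_tensor(rng)
        sys1 = GaitTensor(0.8 * ref.values - 4.0, subjects=ref.subjects)
        report = validity_report(ref, {"depth": sys1})
        wt = report.waveform_table()
        pt = report.parameter_table()
        assert len(wt) == 5
        assert len(pt) == 20
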