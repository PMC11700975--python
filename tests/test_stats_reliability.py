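"""Reliability/validity statistics against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitmono import (generate_cohort, icc_2k, kruskal_wallis, pearson_r,
                      reliability_report, validity_report)
from gaitmono.errors import ParameterError
from gaitmono.pose_model import FEATURE_NAMES, GROUPS


def icc_2k_oracle(M):
    """Raw sums-of-squares two-way ANOVA, written independently."""
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    grand = M.mean()
    ss_between_subj = sum(k * (M[i].mean() - grand) ** 2 for i in range(n))
    ss_between_rater = sum(n * (M[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((x - grand) ** 2 for x in M.ravel())
    ss_resid = ss_total - ss_between_subj - ss_between_rater
    msr = ss_between_subj / (n - 1)
    msc = ss_between_rater / (k - 1)
    mse = ss_resid / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_identical_raters_distinct_subjects_gives_one(self):
        M = np.outer([1.0, 2, 3, 7, 11], np.ones(3))
        res = icc_2k(M)
        assert res.icc == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            M = rng.normal(0, 1, (n, 1)) + rng.normal(0, 1, (n, 3))
            assert icc_2k(M).icc == pytest.approx(icc_2k_oracle(M), abs=1e-9)

    def test_null_concentrates_near_zero(self):
        # no subject effect: the average-measures ICC(2,3) null at n=50
        # is centred on 0 with sampling SD ~0.25
        rng = np.random.default_rng(6)
        iccs = np.array([icc_2k(rng.normal(0, 1, (50, 3))).icc
                         for _ in range(100)])
        assert abs(iccs.mean()) < 0.1
        assert np.mean(np.abs(iccs) < 0.5) >= 0.9

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 15))
            M = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.6, (n, 3))
            long = pd.DataFrame({
                "s": np.repeat(np.arange(n), 3),
                "r": np.tile(np.arange(3), n),
                "v": M.ravel()})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = pg.intraclass_corr(long, targets="s", raters="r",
                                         ratings="v").set_index("Type")
            row = ref.loc["ICC(A,k)"]
            res = icc_2k(M)
            assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
            assert res.p == pytest.approx(row["pval"], abs=1e-9)
            assert res.ci_low == pytest.approx(row["CI95"][0], abs=6e-3)
            assert res.ci_high == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_invariance_under_affine_shift_and_scale(self):
        rng = np.random.default_rng(8)
        M = rng.normal(0, 1, (10, 1)) + rng.normal(0, 0.5, (10, 3))
        base = icc_2k(M).icc
        assert icc_2k(M + 100).icc == pytest.approx(base, abs=1e-9)
        assert icc_2k(M * 7.5).icc == pytest.approx(base, abs=1e-9)

    def test_missing_cells_rejected(self):
        M = np.ones((4, 3))
        M[1, 2] = np.nan
        with pytest.raises(ParameterError):
            icc_2k(M)


class TestPearson:
    def test_perfect_affine_very_high(self):
        x = np.arange(10.0)
        r, band = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and band == "very_high"

    def test_negation_flips_sign(self):
        x = np.arange(10.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, (2, 40))
        expect = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert pearson_r(x, y)[0] == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_invariant_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, (2, 20))
        assert pearson_r(a * x + b, y)[0] == pytest.approx(
            pearson_r(x, y)[0], abs=1e-9)


class TestKruskal:
    def test_identical_groups_h_zero(self):
        g = [1.0, 2, 3]
        res = kruskal_wallis(g, g, g)
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_maximal_rank_separation_significant(self):
        res = kruskal_wallis([1, 2, 3], [101, 102, 103], [201, 202, 203])
        assert res["p"] < 0.05 and res["significant_05"]

    def test_matches_rank_sum_oracle(self):
        from scipy.stats import rankdata
        rng = np.random.default_rng(10)
        groups = [rng.normal(i, 1, rng.integers(5, 12)) for i in range(3)]
        pooled = np.concatenate(groups)
        ranks = rankdata(pooled)
        n = len(pooled)
        start = 0
        H = 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            H += r.sum() ** 2 / len(g)
            start += len(g)
        H = 12 / (n * (n + 1)) * H - 3 * (n + 1)
        # no ties in continuous data -> tie correction is a no-op
        assert kruskal_wallis(*groups)["H"] == pytest.approx(H, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.sampled_from(["exp", "cube", "logistic"]))
    def test_h_invariant_under_monotone_transforms(self, kind):
        rng = np.random.default_rng(2)
        groups = [rng.normal(i * 0.5, 1, 8) for i in range(3)]
        f = {"exp": np.exp, "cube": lambda x: x ** 3,
             "logistic": lambda x: 1 / (1 + np.exp(-x))}[kind]
        a = kruskal_wallis(*groups)["H"]
        b = kruskal_wallis(*[f(g) for g in groups])["H"]
        assert a == pytest.approx(b, abs=1e-9)


@pytest.fixture(scope="module")
def cohort_truth():
    _, truth = generate_cohort((6, 5, 5), seed=21)
    return truth


class TestReports:
    def test_validity_of_identical_tables(self, cohort_truth):
        rep = validity_report(cohort_truth, cohort_truth)
        assert np.allclose(rep["r"], 1.0)
        assert np.allclose(rep["d"], 0.0)
        assert len(rep) == 2 * len(FEATURE_NAMES)  # pd + healthy rows

    def test_validity_detects_key_mismatch(self, cohort_truth):
        with pytest.raises(ParameterError):
            validity_report(cohort_truth, cohort_truth.iloc[:-3])

    def test_reliability_table_shape_and_high_icc(self, cohort_truth):
        rep = reliability_report(cohort_truth)
        assert len(rep) == 3 * len(FEATURE_NAMES)
        assert set(rep["group"]) == set(GROUPS)
        # true features: between-subject variance dominates by design
        assert (rep["icc"] > 0.70).mean() >= 0.9

    def test_noiseless_extraction_correlates_with_truth(self):
        from gaitmono import extract_all, generate_cohort
        seqs, truth = generate_cohort((4, 3, 3), seed=31, noise_sd=0.0)
        rows = []
        for seq in seqs:
            fs = extract_all(seq)
            row = fs.to_row()
            row["subject_id"], row["segment_id"] = seq.subject_id, seq.segment_id
            rows.append(row)
        video = pd.DataFrame(rows)
        video["group"] = truth["group"].to_numpy()
        rep = validity_report(video, truth,
                              feature_names=("single_step_time",))
        assert (rep["r"] > 0.99).all()

    def test_reliability_excludes_incomplete_subjects(self, cohort_truth):
        broken = cohort_truth.iloc[1:]  # one subject loses a segment
        with pytest.warns(UserWarning, match="excluding"):
            rep = reliability_report(broken)
        assert rep["n_subjects"].min() >= 4
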