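"""Risk-allele score, quartile/severity/familial analyses and the
closed-form familial-risk decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from admixfine.riskscore import (
    assign_quartiles,
    build_score,
    control_quartile_cutpoints,
    familial_risk_explained,
    familial_rr_estimate,
    independence_check,
    per_allele_or,
    quartile_analysis,
    severity_case_only_test,
)
from tests.conftest import make_matrix


class TestBuildScore:
    def _score_variants(self, ids, rafs):
        return pd.DataFrame({"variant_id": ids, "raf": rafs})

    def test_all_homozygous_risk_maximum(self):
        dm = make_matrix(np.full((3, 4), 2.0))
        counts = build_score(dm, self._score_variants(dm.variant_ids, [0.5] * 4))
        np.testing.assert_allclose(counts, 8.0)

    def test_missing_contributes_twice_raf(self):
        d = np.array([[1.0, np.nan]])
        dm = make_matrix(d)
        counts = build_score(dm, self._score_variants(["v0", "v1"], [0.5, 0.4]))
        assert counts[0] == pytest.approx(1.0 + 0.8)

    def test_hand_summed_fixture(self):
        rng = np.random.default_rng(31)
        d = rng.integers(0, 3, size=(5, 4)).astype(float)
        d[2, 1] = np.nan
        rafs = [0.2, 0.4, 0.6, 0.8]
        dm = make_matrix(d)
        counts = build_score(dm, self._score_variants(dm.variant_ids, rafs))
        expected = np.where(np.isnan(d), 2 * np.array(rafs), d).sum(axis=1)
        np.testing.assert_allclose(counts, expected, atol=1e-12)

    def test_linear_in_variant_subsets(self):
        rng = np.random.default_rng(32)
        d = rng.integers(0, 3, size=(6, 6)).astype(float)
        dm = make_matrix(d)
        rafs = rng.uniform(0.1, 0.9, 6)
        sv = self._score_variants(dm.variant_ids, rafs)
        whole = build_score(dm, sv)
        part = build_score(dm, sv.iloc[:3]) + build_score(dm, sv.iloc[3:])
        np.testing.assert_allclose(whole, part, atol=1e-12)

    def test_unknown_variant_rejected(self):
        dm = make_matrix(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            build_score(dm, self._score_variants(["nope"], [0.5]))


class TestPerAlleleOR:
    def test_matches_brute_force_ml(self):
        rng = np.random.default_rng(33)
        counts = rng.normal(30, 3, size=30)
        y = (rng.random(30) < 0.5).astype(float)
        res = per_allele_or(counts, y)
        X = np.column_stack([np.ones(30), counts])

        def nll(b):
            eta = X @ b
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        opt = optimize.minimize(nll, np.zeros(2), method="BFGS", tol=1e-14)
        assert res.beta == pytest.approx(opt.x[1], abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            per_allele_or(np.full(20, 30.0), np.repeat([0, 1], 10))


class TestQuartiles:
    def test_uniform_counts_quarter_each(self):
        rng = np.random.default_rng(34)
        counts = rng.uniform(20, 40, size=4000)
        status = np.repeat([0, 1], 2000)
        cut = control_quartile_cutpoints(counts, status)
        q = assign_quartiles(counts, cut)[status == 0]
        for k in (1, 2, 3, 4):
            assert abs((q == k).sum() - 500) <= 1

    def test_quartile_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(35)
        counts = rng.normal(30, 3, size=500)
        status = (rng.random(500) < 0.5).astype(int)
        cut1 = control_quartile_cutpoints(counts, status)
        q1 = assign_quartiles(counts, cut1)
        t = np.exp(counts / 10)  # strictly increasing
        cut2 = control_quartile_cutpoints(t, status)
        q2 = assign_quartiles(t, cut2)
        np.testing.assert_array_equal(q1, q2)

    def test_crude_q4_vs_q1_matches_two_by_two(self):
        rng = np.random.default_rng(36)
        counts = rng.normal(30, 3, size=1200)
        p = 1 / (1 + np.exp(-(counts - 30) * 0.2))
        status = (rng.random(1200) < p).astype(int)
        qa = quartile_analysis(counts, status)
        q = assign_quartiles(counts, qa.cutpoints)
        a = ((q == 4) & (status == 1)).sum()
        b = ((q == 4) & (status == 0)).sum()
        c = ((q == 1) & (status == 1)).sum()
        d = ((q == 1) & (status == 0)).sum()
        or_closed = (a * d) / (b * c)
        got = qa.overall.loc[qa.overall["quartile"] == 4, "or"].iloc[0]
        assert got == pytest.approx(or_closed, rel=1e-6)

    def test_family_history_stratified_reference(self):
        rng = np.random.default_rng(37)
        counts = rng.normal(30, 3, size=800)
        status = (rng.random(800) < 0.5).astype(int)
        fh = rng.choice([0.0, 1.0, np.nan], size=800, p=[0.6, 0.3, 0.1])
        qa = quartile_analysis(counts, status, family_history=fh)
        ref = qa.by_family_history[qa.by_family_history["cell"] == "FH0_Q1"]
        assert ref["or"].iloc[0] == 1.0
        assert len(qa.by_family_history) == 8


class TestSeverity:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            severity_case_only_test(np.arange(10.0), np.ones(10))

    def test_matches_brute_force_ml(self):
        rng = np.random.default_rng(38)
        counts = rng.normal(30, 3, size=40)
        sev = (rng.random(40) < 0.4).astype(float)
        res = severity_case_only_test(counts, sev)
        X = np.column_stack([np.ones(40), counts])

        def nll(b):
            eta = X @ b
            return np.sum(np.log1p(np.exp(eta)) - sev * eta)

        opt = optimize.minimize(nll, np.zeros(2), method="BFGS", tol=1e-14)
        assert np.log(res.odds_ratio) == pytest.approx(opt.x[1], abs=1e-6)

    def test_planted_severity_effect_recovered(self):
        rng = np.random.default_rng(39)
        covered = 0
        for _ in range(20):
            counts = rng.normal(30, 3, size=3000)
            p = 1 / (1 + np.exp(-(-0.8 + 0.05 * (counts - 30))))
            sev = (rng.random(3000) < p).astype(float)
            res = severity_case_only_test(counts, sev)
            if res.ci_lo <= np.exp(0.05) <= res.ci_hi:
                covered += 1
        assert covered >= 16


class TestFamilialRR:
    def test_matches_two_by_two_closed_form(self):
        rng = np.random.default_rng(40)
        fh = (rng.random(2000) < 0.15).astype(float)
        p = np.where(fh == 1, 0.6, 0.45)
        y = (rng.random(2000) < p).astype(float)
        res = familial_rr_estimate(y, fh)
        a = ((fh == 1) & (y == 1)).sum()
        b = ((fh == 1) & (y == 0)).sum()
        c = ((fh == 0) & (y == 1)).sum()
        d = ((fh == 0) & (y == 0)).sum()
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_missing_family_history_dropped(self):
        rng = np.random.default_rng(41)
        fh = rng.choice([0.0, 1.0, np.nan], size=500, p=[0.5, 0.3, 0.2])
        y = (rng.random(500) < 0.5).astype(float)
        res = familial_rr_estimate(y, fh)
        assert res.n == int((~np.isnan(fh)).sum())

    def test_no_variation_rejected(self):
        with pytest.raises(ValueError):
            familial_rr_estimate(np.repeat([0.0, 1.0], 10), np.zeros(20))


class TestFamilialRiskExplained:
    def test_no_case_control_enrichment_explains_nothing(self):
        res = familial_risk_explained(30.0, 30.0, 1.2, 1.55)
        assert res.delta == 0.0
        assert res.rho_score == 1.0
        assert res.fraction == 0.0

    def test_null_per_allele_effect_explains_nothing(self):
        res = familial_risk_explained(30.0, 32.0, 1.0, 1.55)
        assert res.rho_score == 1.0
        assert res.fraction == 0.0

    def test_observed_rr_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            familial_risk_explained(30.0, 32.0, 1.2, 1.0)

    @pytest.mark.parametrize("m1", [31.0, 31.5, 32.0, 33.0])
    def test_monotone_in_case_mean(self, m1):
        lower = familial_risk_explained(30.0, m1 - 0.4, 1.2, 1.55).fraction
        higher = familial_risk_explained(30.0, m1, 1.2, 1.55).fraction
        assert higher > lower

    @pytest.mark.parametrize("lam", [1.05, 1.1, 1.2, 1.4])
    def test_monotone_in_per_allele_or(self, lam):
        lower = familial_risk_explained(30.0, 32.0, lam - 0.03, 1.55).fraction
        higher = familial_risk_explained(30.0, 32.0, lam, 1.55).fraction
        assert higher > lower

    def test_relative_correlation_weighting(self):
        res = familial_risk_explained(30.0, 34.0, 1.2, 1.55, r=0.5)
        assert res.m_rel == pytest.approx(30.0 * 0.75 + 34.0 * 0.25)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        m0=st.floats(10.0, 40.0),
        excess=st.floats(0.01, 8.0),
        lam=st.floats(1.001, 1.5),
        rho_obs=st.floats(1.05, 3.0),
        r=st.floats(0.05, 1.0),
    )
    def test_decomposition_invariants(self, m0, excess, lam, rho_obs, r):
        """For any enrichment of risk alleles in cases and lambda > 1 the
        relatives' mean sits between the control and case means, the
        score-implied RR exceeds 1, and the fraction is positive."""
        res = familial_risk_explained(m0, m0 + excess, lam, rho_obs, r)
        assert m0 <= res.m_rel <= m0 + excess
        assert res.m_rel == pytest.approx(m0 * (1 - r**2) + (m0 + excess) * r**2)
        assert res.rho_score >= 1.0
        assert res.fraction >= 0.0


class TestIndependenceCheck:
    def test_requires_two_variants(self):
        dm = make_matrix(np.random.default_rng(42).integers(0, 3, (20, 3)).astype(float))
        with pytest.raises(ValueError):
            independence_check(dm, ["v0"], np.repeat([0, 1], 10))

    def test_duplicate_variant_flagged_collinear(self):
        rng = np.random.default_rng(43)
        d = rng.integers(0, 3, size=(100, 2)).astype(float)
        d = np.column_stack([d, d[:, 0]])
        dm = make_matrix(d)
        y = (rng.random(100) < 0.5).astype(int)
        res = independence_check(dm, dm.variant_ids, y)
        assert res.collinear == ["v2"]

    def test_independent_variants_have_consistent_betas(self):
        rng = np.random.default_rng(44)
        n = 3000
        g = rng.binomial(2, 0.4, size=(n, 6)).astype(float)
        eta = -0.3 + (g - 0.8) @ np.full(6, 0.15)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        dm = make_matrix(g)
        res = independence_check(dm, dm.variant_ids, y)
        diff = (res.table["beta_joint"] - res.table["beta_single"]).abs()
        assert (diff.median() < 0.5 * res.table["se_single"].median())
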