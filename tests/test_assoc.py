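import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mmpassoc as m
from mmpassoc import study
from mmpassoc.assoc import (
    ContingencyTable2x2,
    association_p,
    crude_model_scan,
    tables_from_counts,
)

from conftest import cohort_from_counts


class TestEncodings:
    @pytest.mark.parametrize(
        "model,expected",
        [
            ("dominant", [0, 1, 1]),
            ("recessive", [0, 0, 1]),
            ("overdominant", [0, 1, 0]),
            ("codominant", [0, 1, 2]),
            ("log_additive", [0, 1, 2]),
        ],
    )
    def test_definitions(self, model, expected):
        out = m.encode_model(np.array([1.0, 2.0, 3.0]), model)
        assert out.tolist() == expected

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            m.encode_model(np.array([1.0]), "multiplicative")

    def test_missing_propagates(self):
        out = m.encode_model(np.array([1.0, np.nan]), "dominant")
        assert out[0] == 0 and np.isnan(out[1])


class TestCrudeOddsRatio:
    def test_published_recessive_row(self):
        est = m.crude_odds_ratio(ContingencyTable2x2(20, 10, 38, 91))
        assert round(est.or_, 2) == 4.79
        assert round(est.ci_low, 2) == 2.05
        assert round(est.ci_high, 2) == 11.19

    def test_symmetric_table(self):
        est = m.crude_odds_ratio(ContingencyTable2x2(1, 1, 1, 1))
        assert est.or_ == pytest.approx(1.0)

    def test_zero_cell_policy(self):
        est = m.crude_odds_ratio(ContingencyTable2x2(0, 19, 30, 110))
        assert est.or_ == 0.0
        assert est.ci_low is None and est.ci_high is None
        assert "zero_cell" in est.flags
        inf_est = m.crude_odds_ratio(ContingencyTable2x2(5, 0, 3, 7))
        assert math.isinf(inf_est.or_)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(st.tuples(*[st.integers(1, 80)] * 4))
    @settings(max_examples=60, derandomize=True)
    def test_reciprocity(self, cells):
        t = ContingencyTable2x2(*cells)
        forward = m.crude_odds_ratio(t).or_
        flipped = m.crude_odds_ratio(t.flipped_exposure()).or_
        assert forward * flipped == pytest.approx(1.0)


class TestWoolfCI:
    def test_published_wide_interval(self):
        low, high = m.woolf_ci(ContingencyTable2x2(3, 1, 39, 89))
        assert (round(low, 2), round(high, 2)) == (0.69, 67.89)

    def test_interval_width_monotone_in_level(self):
        t = ContingencyTable2x2(20, 10, 38, 91)
        widths = []
        for level in (0.5, 0.8, 0.95, 0.999):
            low, high = m.woolf_ci(t, level)
            widths.append(math.log(high) - math.log(low))
        assert widths == sorted(widths)

    def test_zero_cell_gives_no_interval(self):
        assert m.woolf_ci(ContingencyTable2x2(0, 5, 5, 5)) is None

    def test_coverage_near_nominal(self, rng):
        """Woolf intervals cover the true OR in about 95% of simulated
        moderate-count 2x2 tables."""
        true_or, n1, n0, p0 = 2.0, 200, 200, 0.3
        p1 = true_or * p0 / (1 - p0) / (1 + true_or * p0 / (1 - p0))
        hits = trials = 0
        for _ in range(400):
            a = rng.binomial(n1, p1)
            c = n1 - a
            b = rng.binomial(n0, p0)
            d = n0 - b
            if min(a, b, c, d) == 0:
                continue
            low, high = m.woolf_ci(ContingencyTable2x2(a, b, c, d))
            trials += 1
            hits += low <= true_or <= high
        assert 0.91 <= hits / trials <= 0.985


class TestHWE:
    def _enumeration_oracle(self, counts):
        """Exact-fraction sum over all genotype tables with the observed
        allele counts, of probabilities <= the observed table's."""
        n_v, n_het, n_a = counts
        n = n_v + n_het + n_a
        n_minor = 2 * n_a + n_het

        def weight(h):
            a = (n_minor - h) // 2
            b = n - h - a
            return Fraction(
                math.factorial(n) * 2 ** h,
                math.factorial(a) * math.factorial(h) * math.factorial(b),
            )

        hs = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
        weights = {h: weight(h) for h in hs}
        total = sum(weights.values())
        observed = weights[n_het]
        return float(sum(w for w in weights.values() if w <= observed) / total)

    @pytest.mark.parametrize(
        "counts,expected",
        [((104, 50, 6), 1.00), ((128, 28, 4), 0.115), ((48, 81, 30), 0.749)],
    )
    def test_case_group_pvalues(self, counts, expected):
        res = m.hwe_test(counts)
        assert round(res.p_exact, 2 if expected == 1.0 else 3) == expected

    def test_maf_definition(self):
        res = m.hwe_test((104, 50, 6))
        assert res.maf == pytest.approx((2 * 6 + 50) / (2 * 160))

    def test_monomorphic_gives_one(self):
        res = m.hwe_test((50, 0, 0))
        assert res.p_exact == 1.0 and res.p_chisq == 1.0

    @given(
        st.tuples(st.integers(0, 90), st.integers(0, 90), st.integers(0, 90)).filter(
            lambda c: 0 < sum(c) <= 200
        )
    )
    @settings(max_examples=80, derandomize=True)
    def test_exact_p_matches_enumeration(self, counts):
        res = m.hwe_test(counts)
        assert res.p_exact == pytest.approx(self._enumeration_oracle(counts), abs=1e-9)


class TestBHAdjust:
    @staticmethod
    def _step_up_oracle(p):
        p = np.asarray(p, float)
        order = np.argsort(p)
        m_ = len(p)
        adj = np.empty(m_)
        running = 1.0
        for rank in range(m_, 0, -1):
            running = min(running, p[order[rank - 1]] * m_ / rank)
            adj[order[rank - 1]] = running
        return adj

    def test_published_families(self):
        within = m.bh_adjust(study.within_case_p_family())
        assert within[study.within_case_p_family().index(0.0002)] == pytest.approx(
            0.0096
        )
        cc = m.bh_adjust(study.case_control_p_family())
        assert cc[study.case_control_p_family().index(0.011)] == pytest.approx(0.072)

    def test_single_p_unchanged(self):
        assert m.bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.bh_adjust([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_matches_oracle_and_invariants(self, pvals):
        adj = m.bh_adjust(pvals)
        np.testing.assert_allclose(adj, self._step_up_oracle(pvals), atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1).all()
        # order invariance
        rev = m.bh_adjust(pvals[::-1])
        np.testing.assert_allclose(rev[::-1], adj, atol=1e-12)
        # adjusted values are monotone in the raw order statistics
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestLogistic:
    def test_saturated_fit_equals_crude_or(self):
        level0, level1 = study.WITHIN_CASE_COUNTS["rs486055"]["ACLRP"]
        c = cohort_from_counts(level0, level1, snp=study.SNPS[1], outcome="ACLRP")
        crude = crude_model_scan(
            np.array([level0, level1]), "dominant"
        )[0]
        fit = m.logistic_association(c, "rs486055", "ACLRP", "dominant")[0]
        assert fit.or_ == pytest.approx(crude.or_, rel=1e-6)

    def test_codominant_has_two_contrasts_sharing_p(self, null_cohort):
        ests = m.logistic_association(null_cohort, "rs1799750", "status", "codominant")
        assert [e.contrast for e in ests] == ["het_vs_ref", "hom_vs_ref"]
        assert ests[0].p == ests[1].p

    def test_covariate_adjustment_runs(self, null_cohort):
        est = m.logistic_association(
            null_cohort, "rs486055", "status", "dominant", ("age", "body_mass")
        )[0]
        assert est.estimator == "adjusted"
        assert 0 <= est.p <= 1

    def test_separation_is_flagged_not_raised(self, null_cohort):
        c = null_cohort
        c.phenotypes.data["leak"] = c.phenotypes.status.astype(float)
        est = m.logistic_association(c, "rs486055", "status", "dominant", ("leak",))[0]
        assert "separation" in est.flags

    def test_null_type_one_error_calibrated(self):
        """LRT p-values behave like a 5%-level test on genotype-independent
        outcomes."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 150
        for _ in range(reps):
            codes = m.simulate_genotypes(400, 0.3, rng)
            counts = np.array([
                [(codes[:200] == k).sum() for k in (1, 2, 3)],
                [(codes[200:] == k).sum() for k in (1, 2, 3)],
            ])
            est = crude_model_scan(counts, "dominant")[0]
            rejections += est.p < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestScan:
    def test_within_case_family_has_48_cells(self, null_cohort):
        res = m.run_single_locus_scan(
            null_cohort, outcomes=("ACLF", "ACLS", "ACLRP", "ACLRC")
        )
        cells = res.groupby(["snp", "outcome", "model"]).size()
        assert len(cells) == 48
        # codominant carries one p per cell despite two contrasts
        cod = res[res["model"] == "codominant"]
        assert (cod.groupby(["snp", "outcome"])["p"].nunique() == 1).all()

    def test_fdr_within_family_only(self, null_cohort):
        res = m.run_single_locus_scan(
            null_cohort, outcomes=("status", "ACLF")
        )
        for _, block in res.groupby("family"):
            valid = block.dropna(subset=["p_fdr"])
            assert (valid["p_fdr"] >= valid["p"] - 1e-12).all()

    def test_zero_count_levels_flagged_not_fatal(self, panel):
        c = cohort_from_counts((10, 5, 0), (8, 2, 0), snp=panel[2])
        res = m.run_single_locus_scan(c, outcomes=("status",), models=("recessive",))
        assert len(res) == 1
        assert res.iloc[0]["flags"] in ("zero_cell", "")

    def test_2x3_collapse_matches_published_margins(self):
        counts = np.array(study.WITHIN_CASE_COUNTS["rs1799750"]["ACLF"])
        (label, t), = tables_from_counts(counts, "recessive")
        assert (t.a, t.b, t.c, t.d) == (20, 10, 38, 91)
        assert association_p(t) < 0.001
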