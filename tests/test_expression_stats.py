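import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import retromod as rm

from conftest import make_paired_expr, make_unpaired_expr


def _cq_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "cq"])


class TestNormalize:
    def test_one_cycle_difference_doubles_nrq(self):
        cq = _cq_frame(
            [("s1", "t", 1, 20.0), ("s2", "t", 1, 21.0),
             ("s1", "ref", 1, 22.0), ("s2", "ref", 1, 22.0)]
        )
        expr = rm.normalize(cq, ["ref"], efficiency=2.0)
        nrq = expr.set_index("sample_id")["nrq"]
        assert nrq["s1"] / nrq["s2"] == pytest.approx(2.0)

    def test_invariant_to_per_sample_cq_shift(self):
        base = _cq_frame(
            [("s1", "t", 1, 20.0), ("s1", "r1", 1, 22.0), ("s1", "r2", 1, 24.0),
             ("s2", "t", 1, 21.5), ("s2", "r1", 1, 23.0), ("s2", "r2", 1, 23.5)]
        )
        shifted = base.copy()
        shifted.loc[shifted["sample_id"] == "s1", "cq"] += 1.7
        a = rm.normalize(base, ["r1", "r2"]).set_index("sample_id")["nrq"]
        b = rm.normalize(shifted, ["r1", "r2"]).set_index("sample_id")["nrq"]
        assert a["s1"] == pytest.approx(b["s1"], rel=1e-12)

    def test_three_references_match_direct_formula(self):
        """Hand-computed geometric-mean normalization to 12 digits."""
        rows, cqs = [], {}
        rng = np.random.default_rng(8)
        for s in ("s1", "s2"):
            for a in ("t", "r1", "r2", "r3"):
                cq = float(rng.uniform(18, 26))
                cqs[(s, a)] = cq
                rows.append((s, a, 1, cq))
        expr = rm.normalize(_cq_frame(rows), ["r1", "r2", "r3"], efficiency=1.9)
        for s in ("s1", "s2"):
            rq = {a: 1.9 ** (-cqs[(s, a)]) for a in ("t", "r1", "r2", "r3")}
            want = rq["t"] / (rq["r1"] * rq["r2"] * rq["r3"]) ** (1 / 3)
            got = expr.set_index("sample_id")["nrq"][s]
            assert got == pytest.approx(want, rel=1e-12)

    def test_technical_replicates_averaged_on_cq_scale(self):
        cq = _cq_frame(
            [("s1", "t", 1, 20.0), ("s1", "t", 2, 22.0), ("s1", "ref", 1, 20.0),
             ("s2", "t", 1, 21.0), ("s2", "ref", 1, 20.0)]
        )
        nrq = rm.normalize(cq, ["ref"]).set_index("sample_id")["nrq"]
        # mean Cq of s1 is 21 -> equal to s2
        assert nrq["s1"] == pytest.approx(nrq["s2"])

    def test_sample_missing_reference_excluded(self, caplog):
        cq = _cq_frame([("s1", "t", 1, 20.0), ("s1", "ref", 1, 21.0), ("s2", "t", 1, 20.0)])
        expr = rm.normalize(cq, ["ref"])
        assert list(expr["sample_id"]) == ["s1"]


class TestRatioTest:
    def test_uniform_doubling_gives_exact_signed_rank_p(self):
        expr = make_paired_expr([2.0] * 5)
        ratio, p = rm.ratio_test(expr, "paired_genotype")
        assert ratio == pytest.approx(2.0)
        assert p == pytest.approx(1 / 2**5)

    def test_identical_groups_give_unit_ratio_and_p_one(self):
        expr = make_unpaired_expr([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        ratio, p = rm.ratio_test(expr, "unpaired_strain")
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_unpaired_exact_p_matches_permutation_oracle(self):
        """Exact Mann-Whitney p equals brute-force enumeration of all 70
        assignments of 8 values into two groups of 4."""
        rng = np.random.default_rng(5)
        vals = rng.normal(size=8)
        expr = make_unpaired_expr(np.exp(vals[:4]), np.exp(vals[4:]))
        _, p = rm.ratio_test(expr, "unpaired_strain")

        def u_stat(x, y):
            return sum(xi > yi for xi in x for yi in y)

        u_obs = u_stat(np.exp(vals[:4]), np.exp(vals[4:]))
        us = []
        for comb in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in comb]
            us.append(u_stat(vals[list(comb)], vals[rest]))
        us = np.asarray(us)
        want = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert p == pytest.approx(want, rel=1e-12)

    def test_paired_exact_p_matches_sign_enumeration(self):
        """Exact one-sided signed-rank p equals enumeration of all 2^n sign
        assignments for n <= 8."""
        rng = np.random.default_rng(9)
        ratios = np.exp(rng.normal(0.4, 0.5, size=7))
        _, p = rm.ratio_test(make_paired_expr(ratios), "paired_genotype")
        d = np.log(ratios)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [
            sum(r for r, keep in zip(ranks, signs) if keep)
            for signs in itertools.product([0, 1], repeat=len(d))
        ]
        assert p == pytest.approx(np.mean([w >= w_obs for w in ws]), rel=1e-12)

    def test_edited_mode_is_one_sided_increase(self):
        rows = [(f"E{i}", "a", v, "inserted", "edited", "") for i, v in enumerate([3.0, 3.5, 4.0, 5.0])]
        rows += [(f"B{i}", "a", v, "inserted", "B", "") for i, v in enumerate([1.0, 1.2, 1.5, 2.0])]
        expr = pd.DataFrame(rows, columns=["sample_id", "assay_id", "nrq", "strain", "genotype", "pair_id"])
        ratio, p = rm.ratio_test(expr, "unpaired_edited")
        assert ratio > 1
        assert p == pytest.approx(1 / 70)  # most extreme of C(8,4) assignments

    def test_nonpositive_nrq_rejected(self):
        expr = make_paired_expr([2.0] * 3)
        expr.loc[0, "nrq"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            rm.ratio_test(expr, "paired_genotype")


class TestClassFdr:
    def test_reproduces_published_class_q_values(self):
        """BH on the five class-wise p-values reproduces the printed
        q-values within print rounding."""
        p = [2.1e-7, 3.4e-4, 0.43, 0.50, 0.0053]
        q = rm.benjamini_hochberg(p)
        printed = [1.1e-6, 8.6e-4, 0.50, 0.50, 0.0088]
        for qi, pi in zip(q, printed):
            # within half a unit of the last printed digit, plus the
            # rounding already baked into the printed input p-values
            assert qi == pytest.approx(pi, rel=0.02, abs=0.051 * 10 ** np.floor(np.log10(pi)))

    def test_single_p_is_its_own_q(self):
        assert rm.benjamini_hochberg([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_p_all_equal_q(self):
        assert rm.benjamini_hochberg([0.2] * 4) == pytest.approx([0.2] * 4)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, ps):
        q = rm.benjamini_hochberg(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)
        assert np.all((np.asarray(q) >= np.asarray(ps) - 1e-12) & (np.asarray(q) <= 1.0))

    def test_grouping_modes(self):
        df = pd.DataFrame(
            {"assay_id": list("abcd"), "p_cb": [0.01, 0.04, 0.01, 0.04],
             "structural_class": ["x", "x", "y", "y"]}
        )
        by_class = rm.class_fdr(df, "by_class")
        pooled = rm.class_fdr(df, "pooled")
        assert by_class.loc[0, "q"] == pytest.approx(0.02)
        assert pooled.loc[0, "q"] == pytest.approx(0.02)
        assert pooled.loc[1, "q"] == pytest.approx(0.04)


class TestFisherCombined:
    def test_null_inputs_give_one(self):
        assert rm.fisher_combined([1.0, 1.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("pair", [(0.05, 0.05), (0.01, 1.0), (0.3, 0.7), (1e-6, 0.2)])
    def test_matches_closed_form_to_10_digits(self, pair):
        x = -2 * np.sum(np.log(pair))
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert rm.fisher_combined(pair) == pytest.approx(closed, rel=1e-10)

    def test_specific_values(self):
        assert rm.fisher_combined([0.05, 0.05]) == pytest.approx(0.01747866, abs=5e-7)
        assert rm.fisher_combined([0.01, 1.0]) == pytest.approx(0.05605170, abs=5e-7)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            rm.fisher_combined([0.0, 0.5])


class TestGroupwise:
    def test_all_zero_ratios_give_p_one(self):
        assert rm.groupwise_test(np.zeros(10)) == pytest.approx(1.0)

    def test_all_positive_matches_normal_approximation_formula(self):
        d = np.arange(1, 21, dtype=float)
        n = 20
        w = n * (n + 1) / 2
        mu, sig = n * (n + 1) / 4, np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        want = stats.norm.sf((w - mu - 0.5) / sig)
        assert rm.groupwise_test(d) == pytest.approx(want, rel=1e-9)

    def test_sign_flip_symmetry(self):
        """Mirrored data give the mirrored statistic under the same formula,
        and the two one-sided p-values overlap by the continuity point mass."""
        rng = np.random.default_rng(4)
        d = rng.normal(0.3, 1.0, 15)
        n = len(d)
        ranks = stats.rankdata(np.abs(d))
        mu, sig = n * (n + 1) / 4, np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        w_pos = ranks[d > 0].sum()
        w_neg = n * (n + 1) / 2 - w_pos
        p_pos, p_neg = rm.groupwise_test(d), rm.groupwise_test(-d)
        assert p_pos == pytest.approx(stats.norm.sf((w_pos - mu - 0.5) / sig), rel=1e-9)
        assert p_neg == pytest.approx(stats.norm.sf((w_neg - mu - 0.5) / sig), rel=1e-9)
        assert p_pos + p_neg >= 1.0


class TestContextCorrelates:
    def _frame(self, **cols):
        return pd.DataFrame(cols)

    def test_monotone_feature_has_rho_one(self):
        feats = self._frame(length=[1.0, 2, 3, 4, 5, 6])
        out = rm.context_correlates(feats, pd.Series([2.0, 4, 9, 16, 30, 33]))
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_constant_feature_reported_missing_not_zero(self):
        feats = self._frame(flat=[1.0] * 6)
        out = rm.context_correlates(feats, pd.Series([1.0, 2, 3, 4, 5, 6]))
        assert np.isnan(out.loc[0, "rho"]) and np.isnan(out.loc[0, "p"])

    def test_tied_data_matches_average_rank_formula(self):
        x = pd.Series([1, 2, 2, 3, 3, 3, 4, 5], dtype=float)
        y = pd.Series([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0, 6.0])
        out = rm.context_correlates(self._frame(x=x), y)
        want = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert out.loc[0, "rho"] == pytest.approx(want, rel=1e-12)

    def test_categorical_feature_uses_kruskal_wallis(self):
        cat = pd.Series(["alt", "con", "alt", "end", "con", "end", "alt", "con"])
        y = pd.Series([1.0, 5.0, 1.2, 9.0, 5.5, 8.0, 0.9, 5.2])
        out = rm.context_correlates(self._frame(exon=cat), y)
        groups = [y[cat == g].to_numpy() for g in ["alt", "con", "end"]]
        assert out.loc[0, "p"] == pytest.approx(stats.kruskal(*groups).pvalue, rel=1e-12)

    def test_independent_feature_p_values_are_uniform(self):
        """Permutation oracle: under independence the Spearman p-values are
        uniform (KS test at the 0.01 level, 1000 permutations)."""
        rng = np.random.default_rng(123)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(12)
            ps.append(stats.spearmanr(x, y[perm]).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSuppressionAnalysis:
    def test_table_carries_ratios_q_and_meta(self):
        rng = np.random.default_rng(77)
        frames = []
        for assay, c_eff in [("gA", 2.0), ("gB", 1.0)]:
            ui = make_unpaired_expr(np.exp(rng.normal(1, 0.2, 5)), np.exp(rng.normal(0, 0.2, 5)))
            cb = make_paired_expr(c_eff * np.exp(rng.normal(0, 0.1, 8)))
            ui["assay_id"] = assay
            cb["assay_id"] = assay
            frames.append(pd.concat([ui, cb]))
        expr = pd.concat(frames, ignore_index=True)
        out = rm.suppression_analysis(
            expr, {"gA": "full_length", "gB": "solo_LTR"}, extra_pvalues={"gA": 0.04}
        )
        row = out.set_index("assay_id").loc["gA"]
        assert row["c_over_b"] == pytest.approx(2.0, rel=0.2)
        assert row["q"] >= row["p_cb"] - 1e-12
        assert row["p_meta"] == pytest.approx(rm.fisher_combined([row["p_cb"], 0.04]), rel=1e-9)
        assert np.isnan(out.set_index("assay_id").loc["gB", "p_meta"])
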