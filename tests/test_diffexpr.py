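import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from fibroseq.diffexpr import (
    PairedDEModel,
    bh_fdr,
    call_degs,
    classify_specificity,
    cross_species_ratio,
    expression_filter,
    fisher_exact_2x2,
    isoform_concordance,
    kruskal_wallis,
    paired_fold_change,
    paired_t,
)
from fibroseq.simulate import CountSimSpec, simulate_paired_counts


def lines_frame(values_by_line, features=("f1",)):
    return pd.DataFrame(
        {ln: v for ln, v in values_by_line.items()}, index=list(features)
    )


class TestPairedFoldChange:
    def test_doubling_across_all_lines(self):
        t = lines_frame({f"L{i}": [20.0] for i in range(5)})
        c = lines_frame({f"L{i}": [10.0] for i in range(5)})
        out = paired_fold_change(t, c)
        assert out.loc["f1", "fc"] == pytest.approx(2.0)
        assert out.loc["f1", "ln_ratio"] == pytest.approx(0.6931, abs=1e-4)

    def test_identity(self):
        t = lines_frame({"L1": [3.0], "L2": [5.0]})
        out = paired_fold_change(t, t)
        assert out.loc["f1", "fc"] == 1.0 and out.loc["f1", "ln_ratio"] == 0.0

    @given(
        st.lists(st.tuples(st.floats(0.1, 1e4), st.floats(0.1, 1e4)), min_size=2, max_size=6)
    )
    def test_swap_inverts_fc(self, pairs):
        t = lines_frame({f"L{i}": [a] for i, (a, _) in enumerate(pairs)})
        c = lines_frame({f"L{i}": [b] for i, (_, b) in enumerate(pairs)})
        fwd = paired_fold_change(t, c).loc["f1", "fc"]
        rev = paired_fold_change(c, t).loc["f1", "fc"]
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)

    def test_ln_fc_equals_mean_ln_ratio(self):
        rng = np.random.default_rng(3)
        t = lines_frame({f"L{i}": [v] for i, v in enumerate(rng.uniform(1, 100, 5))})
        c = lines_frame({f"L{i}": [v] for i, v in enumerate(rng.uniform(1, 100, 5))})
        out = paired_fold_change(t, c)
        lnrs = [out.loc["f1", f"lnr_L{i}"] for i in range(5)]
        assert math.log(out.loc["f1", "fc"]) == pytest.approx(np.mean(lnrs), rel=1e-12)

    def test_zero_control_without_pseudocount_errors(self):
        t = lines_frame({"L1": [1.0], "L2": [1.0]})
        c = lines_frame({"L1": [0.0], "L2": [1.0]})
        with pytest.raises(ValueError, match="zero control"):
            paired_fold_change(t, c, pseudocount=0.0)


class TestPairedT:
    def test_zero_variance_is_undefined_flag(self):
        assert math.isnan(paired_t([0.0] * 5))

    def test_antisymmetric_pair_gives_p_one(self):
        assert paired_t([1.0, -1.0]) == pytest.approx(1.0)

    def test_matches_closed_form_t(self):
        x = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        t_stat = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        expected = 2 * stats.t.sf(abs(t_stat), df=4)
        assert paired_t(x) == pytest.approx(expected, rel=1e-12)

    def test_matrix_form_matches_rowwise(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 5)))
        ps = paired_t(m)
        for i in range(20):
            assert ps.iloc[i] == pytest.approx(paired_t(m.iloc[i].to_numpy()))


class TestBH:
    def test_hand_computed_stepup(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.005, 0.025, 1 / 30, 0.0375, 0.04])

    def test_single_and_equal(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_nan_excluded_from_ranking(self):
        q = bh_fdr(pd.Series([0.01, np.nan, 0.04]))
        assert math.isnan(q.iloc[1])
        assert np.allclose(q.dropna(), bh_fdr([0.01, 0.04]))


class TestCallDegs:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (2.5, 0.0005, "up"),
            (2.5, 0.002, "none"),
            (0.5, 1e-5, "down"),
            (2.0, 0.0005, "up"),     # FC boundary inclusive
            (1.99, 1e-6, "none"),
            (2.5, 0.001, "none"),    # p boundary strict
            (np.nan, np.nan, "none"),  # undefined test never called
        ],
    )
    def test_rules(self, fc, p, expected):
        frame = pd.DataFrame({"fc": [fc], "p_paired": [p]})
        out, counts = call_degs(frame)
        assert out["call"].iloc[0] == expected


class TestExpressionFilter:
    def test_any_sample_boundary(self):
        m = pd.DataFrame([[0, 0, 10], [0, 0, 0]], index=["a", "b"])
        assert list(expression_filter(m, 10, "any_sample")) == ["a"]

    def test_mean_boundary(self):
        m = pd.DataFrame([[5, 15], [5, 14]], index=["a", "b"])
        assert list(expression_filter(m, 10, "mean")) == ["a"]


class TestSpecificity:
    @pytest.mark.parametrize(
        "fc_p,fc_m,expected",
        [(25, 2, "P_specific"), (8, 4, "shared"), (1, 10, "M_specific")],
    )
    def test_ten_fold_rule(self, fc_p, fc_m, expected):
        assert classify_specificity(fc_p, fc_m) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_specificity(0.0, 2.0)


class TestCrossSpeciesRatio:
    def test_identical_means_ratio_one(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, size=(3, 5))
        out = cross_species_ratio(pd.DataFrame(vals, index=list("abc")),
                                  pd.DataFrame(vals, index=list("abc")))
        assert np.allclose(out["ratio_PM"], 1.0)

    def test_higher_in_p_classification(self):
        """A gene expressed ~15x higher in deermouse lands on the
        higher-in-P side with a small between-species p."""
        rng = np.random.default_rng(4)
        P = pd.DataFrame(rng.normal(14.6, 1.0, size=(1, 5)), index=["Arg1"]).abs()
        M = pd.DataFrame(rng.normal(1.0, 0.1, size=(1, 5)), index=["Arg1"]).abs()
        out = cross_species_ratio(P, M)
        assert out.loc["Arg1", "ratio_PM"] > 10
        assert out.loc["Arg1", "p_between"] < 0.01

    def test_higher_in_m_classification(self):
        rng = np.random.default_rng(4)
        P = pd.DataFrame(rng.normal(1.0, 0.1, size=(1, 5)), index=["Ass1"]).abs()
        M = pd.DataFrame(rng.normal(332.0, 20.0, size=(1, 5)), index=["Ass1"]).abs()
        out = cross_species_ratio(P, M)
        assert 1.0 / out.loc["Ass1", "ratio_PM"] > 100

    def test_unshared_genes_excluded(self):
        P = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        M = pd.DataFrame(np.ones((2, 3)), index=["a", "c"])
        assert list(cross_species_ratio(P, M).index) == ["a"]


class TestIsoformConcordance:
    def test_identity_empty(self):
        calls = pd.Series({"g1": "up", "g2": "none"})
        assert isoform_concordance(calls, calls).empty

    def test_single_discordant_gene_listed(self):
        c1 = pd.Series({"g1": "up", "g2": "none"})
        c2 = pd.Series({"g1": "none", "g2": "none"})
        out = isoform_concordance(c1, c2)
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "call_isoform1"] == "up"

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="g3"):
            isoform_concordance(pd.Series({"g1": "up"}), pd.Series({"g3": "up"}))

    def test_perturbed_gene_is_exactly_discordant(self):
        """Two isoform references identical except one gene's counts:
        exactly that gene discordant at FDR < 0.05."""
        cm, annot, truth = simulate_paired_counts(
            CountSimSpec(n_features=300, frac_deg=0.05, seed=9)
        )
        target = truth.index[truth.is_deg][0]
        counts2 = cm.counts.copy()
        # second isoform reference misses the treatment response of `target`
        ctrl_mean = counts2.loc[target, cm.samples_for("Pleucopus", 0.0)].mean()
        for s in cm.samples_for("Pleucopus"):
            counts2.loc[target, s] = int(ctrl_mean)
        from fibroseq.io import CountMatrix

        res1 = PairedDEModel.from_count_matrix(cm, annot, species="Pleucopus").fit()
        res2 = PairedDEModel.from_count_matrix(
            CountMatrix(counts2, cm.samples), annot, species="Pleucopus"
        ).fit()

        def fdr_calls(res):
            f = res.frame
            sig = (f["q_bh"] < 0.05) & ((f["fc"] >= 2) | (f["fc"] <= 0.5))
            return pd.Series(np.where(sig, np.where(f["fc"] >= 2, "up", "down"), "none"),
                             index=f.index)

        out = isoform_concordance(fdr_calls(res1), fdr_calls(res2))
        assert target in out.index


class TestFisher:
    def test_empty_row_gives_one(self):
        assert fisher_exact_2x2([[0, 7], [0, 11]]) == pytest.approx(1.0)

    def test_perfect_split_enumeration(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / comb(10, 5))

    def test_transpose_invariant(self):
        t = np.array([[3, 7], [9, 2]])
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_matches_full_enumeration(self):
        """Oracle: enumerate every table with the observed margins and sum
        hypergeometric probabilities <= the observed table's."""
        rng = np.random.default_rng(6)
        for _ in range(25):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0 or t.sum() > 30:
                continue
            r1, r2 = t.sum(axis=1)
            c1, _ = t.sum(axis=0)
            n = t.sum()
            probs = []
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs.append(stats.hypergeom.pmf(a, n, r1, c1))
            obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
            expected = sum(p for p in probs if p <= obs * (1 + 1e-7))
            assert fisher_exact_2x2(t) == pytest.approx(expected, rel=1e-8)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestKruskal:
    def test_duplicated_group_h_zero(self):
        g = [1.0, 2.0, 3.0]
        assert kruskal_wallis(g, g) == pytest.approx(1.0)

    def test_constant_data_undefined(self):
        assert math.isnan(kruskal_wallis([1.0, 1.0], [1.0, 1.0]))

    def test_separated_groups_have_maximal_h(self):
        """(1,2,3) vs (4,5,6) attains the largest H over all 3/3 splits of
        the ranks 1..6 — equivalently the smallest p."""
        from itertools import combinations

        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        p_obs = kruskal_wallis([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        for idx in combinations(range(6), 3):
            g1 = [vals[i] for i in idx]
            g2 = [vals[i] for i in range(6) if i not in idx]
            assert kruskal_wallis(g1, g2) >= p_obs - 1e-12

    def test_statistic_matches_rank_oracle(self):
        """H recomputed directly from the tie-corrected rank formula."""
        rng = np.random.default_rng(8)
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (5, 7, 6)]
        flat = np.concatenate(groups)
        ranks = stats.rankdata(flat)
        n = flat.size
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start : start + g.size]
            h += r.sum() ** 2 / g.size
            start += g.size
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(flat, return_counts=True)
        h /= 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        expected = stats.chi2.sf(h, df=2)
        assert kruskal_wallis(*groups) == pytest.approx(expected, rel=1e-10)


class TestPairedDEModel:
    def test_planted_positive_effects_yield_more_up_calls(self):
        cm, annot, truth = simulate_paired_counts(
            CountSimSpec(n_features=800, frac_deg=0.1, seed=2)
        )
        res = PairedDEModel.from_count_matrix(
            cm, annot, species="Mmusculus", reference="Gapdh"
        ).fit()
        assert res.n_up > res.n_down
        assert "upregulated DEGs" in res.summary()

    def test_housekeeping_gene_is_stable_under_null(self):
        """With no planted effects the library-level chain leaves Gapdh
        near fold change 1; with planted effects the Gapdh-ratio chain
        pins it at exactly 1 (it is its own reference)."""
        cm, annot, _ = simulate_paired_counts(
            CountSimSpec(n_features=800, frac_deg=0.0, seed=2)
        )
        res = PairedDEModel.from_count_matrix(
            cm, annot, species="Pleucopus", reference=None
        ).fit()
        assert 0.8 < res.frame.loc["Gapdh", "fc"] < 1.25
        assert res.frame.loc["Gapdh", "call"] == "none"

        cm2, annot2, _ = simulate_paired_counts(
            CountSimSpec(n_features=800, frac_deg=0.1, seed=2)
        )
        res2 = PairedDEModel.from_count_matrix(
            cm2, annot2, species="Pleucopus", reference="Gapdh"
        ).fit()
        assert res2.frame.loc["Gapdh", "fc"] == pytest.approx(1.0)

    def test_recall_changes_thresholds_not_fit(self):
        cm, annot, _ = simulate_paired_counts(CountSimSpec(n_features=400, seed=5))
        res = PairedDEModel.from_count_matrix(cm, annot, species="Pleucopus").fit()
        loose = res.recall(p_max=0.05)
        assert loose.n_up >= res.n_up
        pd.testing.assert_series_equal(loose.frame["fc"], res.frame["fc"])
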