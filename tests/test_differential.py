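"""Differential editing statistics, Fisher/odds-ratio machinery, TPM."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from editscan.differential import (
    ContingencyTable2x2,
    EditingMatrix,
    compare_expression,
    compare_groups,
    detection_overlap,
    fisher_exact_two_sided,
    multi_event_enrichment,
    odds_ratio_with_ci,
    pca_events,
    spearman_correlation,
    tpm_from_counts,
)


def mk_matrix(rows: dict, groups: dict) -> EditingMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    return EditingMatrix(df, pd.Series(groups))


GROUPS = {"a1": "g1", "a2": "g1", "a3": "g1", "b1": "g2", "b2": "g2", "b3": "g2"}


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        mat = mk_matrix({"e1": dict(a1=.1, a2=.2, a3=.3, b1=.1, b2=.2, b3=.3)},
                        GROUPS)
        res = compare_groups(mat, "g1", "g2")
        assert res.loc["e1", "t"] == pytest.approx(0.0)
        assert res.loc["e1", "p"] == pytest.approx(1.0)
        assert not res.loc["e1", "significant"]

    def test_zero_pooled_variance_convention(self):
        mat = mk_matrix({"same": dict(a1=.1, a2=.1, a3=.1, b1=.1, b2=.1, b3=.1),
                         "diff": dict(a1=.1, a2=.1, a3=.1, b1=.5, b2=.5, b3=.5)},
                        GROUPS)
        res = compare_groups(mat, "g1", "g2")
        assert res.loc["same", "p"] == 1.0 and res.loc["same", "degenerate"]
        assert res.loc["diff", "p"] == 0.0 and res.loc["diff", "degenerate"]
        assert res.loc["diff", "direction"] == "up"

    def test_pooled_t_matches_closed_form(self):
        x = np.array([0.10, 0.15, 0.12])
        y = np.array([0.30, 0.28, 0.35])
        mat = mk_matrix({"e": dict(zip(GROUPS, np.r_[x, y]))}, GROUPS)
        res = compare_groups(mat, "g1", "g2")
        # independent closed-form pooled-variance Student's t
        sp2 = (x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4
        t = (y.mean() - x.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert res.loc["e", "t"] == pytest.approx(t)
        assert res.loc["e", "p"] == pytest.approx(p)

    def test_label_swap_flips_direction_preserves_p(self):
        rng = np.random.default_rng(3)
        rows = {f"e{i}": dict(zip(GROUPS, rng.uniform(0, 1, 6))) for i in range(8)}
        mat = mk_matrix(rows, GROUPS)
        fwd = compare_groups(mat, "g1", "g2")
        rev = compare_groups(mat, "g2", "g1")
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["t"], -rev["t"])
        flip = {"up": "down", "down": "up", "none": "none"}
        assert all(rev.loc[e, "direction"] == flip[fwd.loc[e, "direction"]]
                   for e in fwd.index)

    def test_missing_values_below_min_n_untestable(self):
        mat = mk_matrix({"e": dict(a1=.1, b1=.2, b2=.3)}, GROUPS)
        res = compare_groups(mat, "g1", "g2", min_n=2)
        assert not res.loc["e", "testable"]
        assert not res.loc["e", "significant"]

    def test_absent_group_rejected(self):
        mat = mk_matrix({"e": dict(a1=.1)}, {"a1": "g1"})
        with pytest.raises(ValueError, match="absent"):
            compare_groups(mat, "g1", "nope")

    def test_recovery_of_shifted_events(self):
        """Events shifted by 0.2 (0.1 -> 0.3) with binomial noise at depth 50
        are recovered at >= 80% power, with ~5% false positives on nulls."""
        rng = np.random.default_rng(42)
        depth, n = 50, 3
        rows, truth = {}, {}
        for i in range(60):
            shifted = i < 20
            p1, p2 = (0.1, 0.3) if shifted else (0.2, 0.2)
            vals = np.r_[rng.binomial(depth, p1, n), rng.binomial(depth, p2, n)] / depth
            rows[f"e{i}"] = dict(zip(GROUPS, vals))
            truth[f"e{i}"] = shifted
        res = compare_groups(mk_matrix(rows, GROUPS), "g1", "g2")
        sig = set(res.index[res["significant"]])
        hits = sum(1 for e, is_shift in truth.items() if is_shift and e in sig)
        false = sum(1 for e, is_shift in truth.items() if not is_shift and e in sig)
        assert hits / 20 >= 0.8
        assert false / 40 <= 0.125


class TestOverlap:
    def test_identical_and_disjoint(self):
        assert detection_overlap({1, 2}, {1, 2})["frac_shared"] == 1.0
        assert detection_overlap({1}, {2})["shared"] == 0

    def test_enumeration(self):
        out = detection_overlap({"x", "y", "z"}, {"y", "z", "w"})
        assert (out["shared"], out["a_only"], out["b_only"]) == (2, 1, 1)
        assert out["shared"] + out["a_only"] + out["b_only"] == out["union"]

    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    @settings(max_examples=100, deadline=None)
    def test_union_conserved_and_symmetric(self, a, b):
        out = detection_overlap(a, b)
        assert out["shared"] + out["a_only"] + out["b_only"] == len(a | b)
        rev = detection_overlap(b, a)
        assert rev["shared"] == out["shared"]
        assert rev["a_only"] == out["b_only"]
        if a | b:
            assert (out["frac_shared"] + out["frac_a_only"] + out["frac_b_only"]
                    == pytest.approx(1.0))


class TestPCA:
    def test_rank_one_structure(self):
        mat = mk_matrix({"e1": dict(a1=.1, a2=.1, a3=.1, b1=.5, b2=.5, b3=.5),
                         "e2": dict(a1=.2, a2=.2, a3=.2, b1=.2, b2=.2, b3=.2)},
                        GROUPS)
        _, frac = pca_events(mat)
        assert frac[0] == pytest.approx(1.0)

    def test_identical_samples_degenerate(self):
        mat = mk_matrix({"e1": dict(a1=.1, b1=.1)},
                        {"a1": "g1", "b1": "g2"})
        with pytest.raises(ValueError, match="degenerate"):
            pca_events(mat)

    def test_single_sample_rejected(self):
        mat = mk_matrix({"e1": dict(a1=.1)}, {"a1": "g1"})
        with pytest.raises(ValueError, match="2 samples"):
            pca_events(mat)

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(5)
        rows = {f"e{i}": dict(zip(GROUPS, rng.uniform(0, 1, 6))) for i in range(10)}
        mat = mk_matrix(rows, GROUPS)
        scores, frac = pca_events(mat)
        X = mat.levels.to_numpy().T
        X = X - X.mean(axis=0)
        eigvals = np.linalg.eigvalsh(X @ X.T)[::-1]
        eigvals = eigvals[eigvals > 1e-12]
        assert np.allclose(frac[:len(eigvals)], eigvals / eigvals.sum(), atol=1e-9)
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(frac >= 0)

    def test_mean_imputation_fills_missing(self):
        mat = mk_matrix({"e1": dict(a1=.1, a2=np.nan, a3=.3, b1=.5, b2=.5, b3=.5),
                         "e2": dict(a1=.2, a2=.2, a3=.2, b1=.3, b2=.3, b3=.3)},
                        GROUPS)
        scores, frac = pca_events(mat)
        assert np.all(np.isfinite(scores.to_numpy()))


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_correlation(x, x) == pytest.approx(1.0)
        assert spearman_correlation(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_hand_ranking(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [1.0, 3.0, 2.0, 4.0]
        # hand-average ranks: x -> 1, 2.5, 2.5, 4 ; y -> 1, 3, 2, 4
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 3, 2, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y) == pytest.approx(expected)

    def test_constant_vector_is_nan(self):
        assert np.isnan(spearman_correlation([1, 1, 1], [1, 2, 3]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 2], [1, 2])


def _oracle_fisher(a, b, c, d) -> float:
    """Independent enumeration oracle: exact-rational hypergeometric pmf via a
    multiplicative recurrence, two-sided by summing pmf <= observed."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {}
    cur = Fraction(1)
    # start at k = lo with weight C(r1,lo)*C(r2,c1-lo), built multiplicatively
    for j in range(lo):
        cur *= Fraction(r1 - j, j + 1)
    for j in range(c1 - lo):
        cur *= Fraction(r2 - j, j + 1)
    pmf[lo] = cur
    for k in range(lo, hi):
        cur = cur * Fraction((r1 - k) * (c1 - k), (k + 1) * (r2 - c1 + k + 1))
        pmf[k + 1] = cur
    total = sum(pmf.values())
    obs = pmf[a]
    return float(sum(w for w in pmf.values() if w <= obs) / total)


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_diagonal_table_matches_enumeration(self):
        t = ContingencyTable2x2(10, 0, 0, 10)
        assert fisher_exact_two_sided(t) == pytest.approx(
            _oracle_fisher(10, 0, 0, 10), rel=1e-12)

    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_and_oracle(self, a, b, c, d):
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(_oracle_fisher(a, b, c, d), rel=1e-10, abs=1e-12)
        _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)


class TestOddsRatio:
    def test_identity_table(self):
        orr, lo, hi, corrected = odds_ratio_with_ci(ContingencyTable2x2(5, 5, 5, 5))
        assert orr == pytest.approx(1.0) and not corrected
        assert lo < 1.0 < hi

    def test_row_swap_inverts(self):
        t = ContingencyTable2x2(20, 10, 5, 15)
        swapped = ContingencyTable2x2(5, 15, 20, 10)
        orr, lo, hi, _ = odds_ratio_with_ci(t)
        orr2, lo2, hi2, _ = odds_ratio_with_ci(swapped)
        assert orr2 == pytest.approx(1 / orr)
        assert lo2 == pytest.approx(1 / hi) and hi2 == pytest.approx(1 / lo)

    def test_zero_cell_corrected(self):
        orr, lo, hi, corrected = odds_ratio_with_ci(ContingencyTable2x2(10, 0, 3, 5))
        assert corrected and np.isfinite(orr) and lo > 0

    def test_matches_statsmodels_woolf_interval(self):
        from statsmodels.stats.contingency_tables import Table2x2
        t = ContingencyTable2x2(30, 12, 7, 21)
        orr, lo, hi, _ = odds_ratio_with_ci(t)
        sm = Table2x2([[30, 12], [7, 21]])
        assert orr == pytest.approx(sm.oddsratio)
        sm_lo, sm_hi = sm.oddsratio_confint(0.05)
        assert lo == pytest.approx(sm_lo) and hi == pytest.approx(sm_hi)


class TestEnrichment:
    def test_table_construction(self):
        counts = {"X": 1, "Y": 3, "Z": 1, "W": 2}
        res = multi_event_enrichment(counts, {"X", "Y"})
        assert res.table.cells == (1, 1, 1, 1)
        assert res.p == 1.0

    def test_no_differential_genes_corrected(self):
        res = multi_event_enrichment({"X": 1, "Y": 2}, set())
        assert res.corrected
        assert res.table.c == 0 and res.table.d == 0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            multi_event_enrichment({}, set())

    def test_planted_odds_ratio_recovered(self):
        """Genes made differential with count-dependent odds ~2.5 yield an
        estimated OR whose CI covers the planted value."""
        rng = np.random.default_rng(9)
        planted_or = 2.5
        p_single = 0.05
        odds_multi = planted_or * p_single / (1 - p_single)
        p_multi = odds_multi / (1 + odds_multi)
        counts, diff = {}, set()
        for i in range(2500):
            gene = f"g{i}"
            multi = i % 3 == 0
            counts[gene] = 3 if multi else 1
            if rng.random() < (p_multi if multi else p_single):
                diff.add(gene)
        res = multi_event_enrichment(counts, diff)
        assert res.ci_low <= planted_or <= res.ci_high


class TestTPM:
    def test_single_gene_gets_everything(self):
        tpm = tpm_from_counts({"g": 7}, {"g": 500})
        assert tpm["g"] == pytest.approx(1e6)

    def test_length_normalization(self):
        tpm = tpm_from_counts({"a": 10, "b": 10}, {"a": 1000, "b": 2000})
        assert tpm["a"] / tpm["b"] == pytest.approx(2.0)

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(2)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 500, 50))}
        lengths = {f"g{i}": int(l) for i, l in enumerate(rng.integers(200, 5000, 50))}
        tpm = tpm_from_counts(counts, lengths)
        assert tpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_all_zero_counts_warns(self):
        with pytest.warns(UserWarning):
            tpm = tpm_from_counts({"a": 0, "b": 0}, {"a": 100, "b": 100})
        assert (tpm == 0).all()

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            tpm_from_counts({"a": 1}, {"a": 0})


class TestCompareExpression:
    def test_identical_groups_p_one(self):
        tpm = pd.DataFrame({s: [100.0, 50.0] for s in GROUPS}, index=["gX", "gY"])
        res = compare_expression(tpm, GROUPS, "g1", "g2")
        assert res["degenerate"].all()
        assert (res["p"] == 1.0).all()

    def test_twofold_change_power(self):
        """A 2x expression change with 10% CV at n=3/group is detected in at
        least 90% of simulations."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            base = 100 * rng.normal(1, 0.1, 3)
            up = 200 * rng.normal(1, 0.1, 3)
            tpm = pd.DataFrame({**{f"a{i+1}": [base[i]] for i in range(3)},
                                **{f"b{i+1}": [up[i]] for i in range(3)}},
                               index=["g"])
            res = compare_expression(tpm, GROUPS, "g1", "g2")
            hits += bool(res.loc["g", "significant"])
        assert hits / n_sim >= 0.9


class TestEditingMatrixContract:
    def test_levels_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            mk_matrix({"e": dict(a1=1.5)}, {"a1": "g1"})

    def test_unlabeled_sample_rejected(self):
        with pytest.raises(ValueError, match="group label"):
            mk_matrix({"e": dict(a1=0.5)}, {"zz": "g1"})

    def test_tsv_round_trip(self, tmp_path):
        mat = mk_matrix({"e1": dict(a1=.1, a2=np.nan, a3=.3, b1=.5, b2=.5, b3=.5)},
                        GROUPS)
        path = tmp_path / "m.tsv"
        mat.to_tsv(path)
        back = EditingMatrix.from_tsv(path, GROUPS)
        pd.testing.assert_frame_equal(mat.levels, back.levels, check_names=False)
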