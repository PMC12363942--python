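"""Repeat parsing, TE proportions, enrichment statistics and PGLS."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from amyloc.architecture import DatedTree
from amyloc.errors import InvalidInputError, ParseError, UndefinedValueError
from amyloc.synthetic import simulate_bm_traits, simulate_ultrametric_tree
from amyloc.te_landscape import (
    RepeatAnnotation,
    bh_adjust,
    log2_enrichment,
    parse_repeat_annotations,
    pgls_fit,
    spearman_partial,
    te_proportion,
    wilcoxon_signed_rank,
)

MASKER_HEADER = (
    "   SW   perc perc perc  query     position in query    matching "
    "repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat    "
    "class/family  begin end  (left) ID\n"
    "\n"
)

MASKER_BODY = """\
  463   11.4  0.0  0.0  chr1   101   400  (599)   +  AluY       SINE/Alu        1  300  (0)   1
 1200    5.0  0.1  0.2  chr1   500   900  (99)    C  L1PA4      LINE/L1         1  401  (0)   2
  300    8.0  0.0  0.0  chr1   950   980  (19)    +  MER4       LTR/ERV1        1   31  (0)   3
  210    2.0  0.0  0.0  chr1   985   995  (4)     +  Charlie1   DNA/hAT-Charlie 1   11  (0)   4
  100    1.0  0.0  0.0  chr1   996   999  (0)     +  (AT)n      Simple_repeat   1    4  (0)   5
"""


class TestRepeatParser:
    def test_coordinate_conversion(self, tmp_path):
        """1-based inclusive printed coordinates become 0-based half-open."""
        p = tmp_path / "one.out"
        p.write_text(MASKER_HEADER + MASKER_BODY.splitlines()[0] + "\n")
        (ann,) = parse_repeat_annotations(str(p))
        assert ann.interval == (100, 400)
        assert ann.te_class == "SINE"
        assert ann.family == "AluY"

    def test_empty_body(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text(MASKER_HEADER)
        assert parse_repeat_annotations(str(p)) == []

    def test_mixed_rows_match_hand_parse(self, tmp_path):
        p = tmp_path / "mixed.out"
        p.write_text(MASKER_HEADER + MASKER_BODY)
        anns = parse_repeat_annotations(str(p))
        expected = [
            ((100, 400), "SINE"),
            ((499, 900), "LINE"),
            ((949, 980), "LTR"),
            ((984, 995), "DNA"),
            ((995, 999), "other"),
        ]
        assert [(a.interval, a.te_class) for a in anns] == expected

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(MASKER_HEADER + "garbage row\n")
        with pytest.raises(ParseError, match="line 4"):
            parse_repeat_annotations(str(p))


def _ann(start, end):
    return RepeatAnnotation((start, end), "f", "SINE", "t")


class TestTEProportion:
    def test_no_annotations(self):
        assert te_proportion([], 1000) == 0.0

    def test_overlap_union_not_double_counted(self):
        assert te_proportion([_ann(0, 100), _ann(50, 150)], 1000) == pytest.approx(0.15)

    def test_full_cover(self):
        assert te_proportion([_ann(0, 500)], 500) == 1.0

    def test_split_invariance(self, rng):
        """Splitting an annotation into abutting halves never changes the
        proportion."""
        whole = [_ann(10, 200), _ann(300, 450)]
        split = [_ann(10, 100), _ann(100, 200), _ann(300, 375), _ann(375, 450)]
        assert te_proportion(whole, 500) == te_proportion(split, 500)

    def test_out_of_region_rejected(self):
        with pytest.raises(InvalidInputError):
            te_proportion([_ann(900, 1100)], 1000)


class TestLog2Enrichment:
    def test_equal_proportions(self):
        assert log2_enrichment(0.1, 0.1, pseudo=0) == 0.0

    def test_doubling(self):
        assert log2_enrichment(0.2, 0.1, pseudo=0) == pytest.approx(1.0)

    def test_zero_locus_with_pseudocount(self):
        assert log2_enrichment(0.0, 0.05, pseudo=1e-4) == pytest.approx(
            math.log2(1e-4 / 0.0501)
        )

    def test_undefined_without_pseudocount(self):
        with pytest.raises(UndefinedValueError):
            log2_enrichment(0.0, 0.0, pseudo=0.0)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        """Five positive distinct differences: exact two-sided p = 2/2^5."""
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(0.0625)

    def test_antisymmetric_differences(self):
        assert wilcoxon_signed_rank([3, -3, 7, -7]) == 1.0

    def test_all_zero_differences(self):
        assert wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration(self, seed):
        """n = 8 random differences against full 2^8 sign enumeration."""
        rng = np.random.default_rng(seed)
        diffs = rng.normal(size=8)
        ranks = stats.rankdata(np.abs(diffs))
        total = ranks.sum()
        w = ranks[diffs > 0].sum()
        lo, hi = min(w, total - w), max(w, total - w)
        count = 0
        for signs in itertools.product((1, -1), repeat=8):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w_plus <= lo + 1e-9 or w_plus >= hi - 1e-9:
                count += 1
        assert wilcoxon_signed_rank(list(diffs)) == pytest.approx(count / 2**8)

    def test_ties_are_midranked_exactly(self):
        diffs = [1.0, 1.0, -1.0, 2.0, 2.0, 3.0]
        ranks = stats.rankdata(np.abs(diffs))
        total = ranks.sum()
        w = ranks[np.array(diffs) > 0].sum()
        lo, hi = min(w, total - w), max(w, total - w)
        count = 0
        for signs in itertools.product((1, -1), repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
            if w_plus <= lo + 1e-9 or w_plus >= hi - 1e-9:
                count += 1
        assert wilcoxon_signed_rank(diffs) == pytest.approx(count / 2**6)

    def test_large_n_normal_approximation(self, rng):
        diffs = rng.normal(loc=0.5, size=60)
        p = wilcoxon_signed_rank(list(diffs))
        ref = stats.wilcoxon(diffs, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_enrichment_sign_rejection(self):
        """Locus proportions strictly above genome proportions reject at
        alpha = 0.05 for n >= 10 in nearly all seeds."""
        rejected = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            genome = rng.uniform(0.1, 0.4, size=12)
            locus = genome + rng.uniform(0.01, 0.1, size=12)
            if wilcoxon_signed_rank(list(locus - genome)) < 0.05:
                rejected += 1
        assert rejected >= 38


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_formula(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=12)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            q_sorted[rank] = running
        expected = np.empty(m)
        expected[order] = q_sorted
        np.testing.assert_allclose(bh_adjust(list(p)), expected)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=20)
        q = bh_adjust(list(p))
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.2])


class TestSpearmanPartial:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.uniform(size=20)
        res = spearman_partial(list(x), list(np.exp(x)), list(rng.uniform(size=20)))
        assert res.rho == pytest.approx(1.0)

    def test_hand_ranked_six_points(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 0.5]
        z = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        expected_rho = np.corrcoef(rx, ry)[0, 1]
        design = np.column_stack([np.ones(6), rz])
        res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        expected_partial = np.corrcoef(res_x, res_y)[0, 1]
        res = spearman_partial(x, y, z)
        assert res.rho == pytest.approx(expected_rho)
        assert res.partial_rho == pytest.approx(expected_partial)

    def test_conditional_independence_partial_near_zero(self):
        """x and y that only share a confounder z have partial correlation
        near zero (averaged over 50 seeds at n = 200)."""
        partials = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=200)
            x = z + rng.normal(size=200)
            y = z + rng.normal(size=200)
            partials.append(spearman_partial(list(x), list(y), list(z)).partial_rho)
        assert abs(np.mean(partials)) < 0.15

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedValueError):
            spearman_partial([1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1])


class TestPGLS:
    def test_star_phylogeny_equals_ols(self, rng):
        n = 16
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        tree = DatedTree.from_newick(newick)
        x = {f"t{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
        y = {t: 2.0 * v + rng.normal() for t, v in x.items()}
        fit = pgls_fit(tree, x, y)
        xs = np.array([x[f"t{i}"] for i in range(n)])
        ys = np.array([y[f"t{i}"] for i in range(n)])
        slope, intercept = np.polyfit(xs, ys, 1)
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)

    def test_loglik_at_optimum_dominates_endpoints(self):
        tree = simulate_ultrametric_tree(30, seed=3, height=5.0)
        x, y, _ = simulate_bm_traits(tree, 0.7, 1.0, 0.0, 1.0, 0.3, seed=4)
        from amyloc.te_landscape import _gls_profile, _lambda_cov, phylogenetic_covariance

        tips = sorted(tree.tip_labels)
        C = phylogenetic_covariance(tree, tips)
        X = np.column_stack([np.ones(len(tips)), [x[t] for t in tips]])
        yv = np.array([y[t] for t in tips])
        fit = pgls_fit(tree, x, y)
        ll0 = _gls_profile(X, yv, _lambda_cov(C, 0.0))[2]
        ll1 = _gls_profile(X, yv, _lambda_cov(C, 1.0))[2]
        assert fit.loglik >= ll0 - 1e-8
        assert fit.loglik >= ll1 - 1e-8

    def test_brownian_recovery_small(self):
        """Mean slope near truth and high lambda on a reduced replicate set
        (the full-scale recovery lives in the acceptance suite)."""
        slopes, lams = [], []
        for rep in range(20):
            tree = simulate_ultrametric_tree(60, seed=700 + rep, height=10.0)
            x, y, _ = simulate_bm_traits(tree, 1.0, 1.0, 0.5, 2.0, 0.1, seed=rep)
            fit = pgls_fit(tree, x, y)
            slopes.append(fit.slope)
            lams.append(fit.lam)
        assert np.mean(slopes) == pytest.approx(2.0, abs=0.15)
        assert np.mean(lams) >= 0.85

    def test_mismatched_tips_rejected(self):
        tree = simulate_ultrametric_tree(5, seed=1)
        x = {t: 0.0 for t in tree.tip_labels}
        y = dict(x)
        y.pop(sorted(y)[0])
        y["not_a_tip"] = 1.0
        with pytest.raises(InvalidInputError):
            pgls_fit(tree, x, y)
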