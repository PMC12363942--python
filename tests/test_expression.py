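"""Diagnostic-site selection, read assignment and count post-processing."""

import numpy as np
import pandas as pd
import pytest

from amyloc.errors import InvalidInputError, UndefinedValueError
from amyloc.expression import (
    ParalogAlignment,
    assign_reads,
    consensus_from_alignment,
    filter_low_expression,
    find_diagnostic_sites,
    log2_fold_change,
    median_of_ratios_size_factors,
    proportional_expression,
)
from amyloc.synthetic import simulate_reads

from conftest import mutate, random_seq


def _paralog_triplet_with_printed_table(rng):
    """Three paralogs whose only informative columns sit at CDS positions
    93, 111, 737 and 753 (1-based) with the allele rows of the published
    diagnostic table: AMY2B = G,T,A,T; AMYm = A,G,T,T; AMY1' = A,T,T,C."""
    backbone = random_seq(rng, 800)
    rows = {
        "AMY2B": ("G", "T", "A", "T"),
        "AMYm": ("A", "G", "T", "T"),
        "AMY1p": ("A", "T", "T", "C"),
    }
    columns = [92, 110, 736, 752]  # 0-based
    seqs = {}
    for pid, alleles in rows.items():
        s = list(backbone)
        for col, allele in zip(columns, alleles):
            s[col] = allele
        seqs[pid] = "".join(s)
    return ParalogAlignment(list(seqs), list(seqs.values())), columns, rows


class TestFindDiagnosticSites:
    def test_printed_allele_table_recovered(self, rng):
        aln, columns, rows = _paralog_triplet_with_printed_table(rng)
        sites = find_diagnostic_sites(aln)
        assert sorted(sites.sites) == columns
        for pid, alleles in rows.items():
            assert sites.pattern(pid) == alleles
        assert sites.proximal_count == 2 and sites.distal_count == 2

    def test_single_informative_column(self, rng):
        backbone = random_seq(rng, 200)
        other = backbone[:50] + ("A" if backbone[50] != "A" else "C") + backbone[51:]
        aln = ParalogAlignment(["p1", "p2"], [backbone, other])
        sites = find_diagnostic_sites(aln)
        assert sorted(sites.sites) == [50]

    def test_identical_paralogs_rejected(self, rng):
        s = random_seq(rng, 300)
        with pytest.raises(UndefinedValueError):
            find_diagnostic_sites(ParalogAlignment(["a", "b"], [s, s]))

    def test_gap_columns_excluded(self):
        aln = ParalogAlignment(["a", "b"], ["AC-GTACGT", "ACTGTACGA"])
        sites = find_diagnostic_sites(aln)
        assert 2 not in sites.sites

    @pytest.mark.parametrize("seed", range(50))
    def test_joint_patterns_unique_on_random_alignments(self, seed):
        """2% diverged random triplets always yield uniquely identifying
        joint patterns (checked by exhaustive pattern comparison)."""
        rng = np.random.default_rng(seed)
        base = random_seq(rng, 500)
        aln = ParalogAlignment(
            ["p1", "p2", "p3"], [mutate(rng, base, 0.02) for _ in range(3)]
        )
        sites = find_diagnostic_sites(aln)
        patterns = {sites.pattern(p) for p in aln.paralog_ids}
        assert len(patterns) == 3


class TestAssignReads:
    def test_printed_table_read_assignment(self, rng):
        """A read spanning positions 93 and 111 carrying A,G belongs to the
        paralog with that printed allele pair (AMYm)."""
        aln, columns, rows = _paralog_triplet_with_printed_table(rng)
        sites = find_diagnostic_sites(aln)
        consensus = consensus_from_alignment(aln)
        read = aln.rows[aln.paralog_ids.index("AMYm")][60:210]
        counts = assign_reads([read], consensus, sites)
        assert counts.counts == {"AMY2B": 0, "AMYm": 1, "AMY1p": 0}

    def test_read_without_sites_unassigned(self, rng):
        aln, columns, _ = _paralog_triplet_with_printed_table(rng)
        sites = find_diagnostic_sites(aln)
        consensus = consensus_from_alignment(aln)
        read = consensus[300:450]  # overlaps no diagnostic site
        counts = assign_reads([read], consensus, sites)
        assert counts.assigned_total == 0
        assert counts.unassigned == 1

    def test_shared_allele_read_never_assigned(self, rng):
        """A read matching two paralogs at every covered site stays
        unassigned rather than being arbitrarily allocated."""
        aln, columns, rows = _paralog_triplet_with_printed_table(rng)
        sites = find_diagnostic_sites(aln)
        consensus = consensus_from_alignment(aln)
        # at 737/753 AMYm carries T,T and AMY1' T,C; a read covering only
        # column 737 with T is compatible with both
        read = aln.rows[aln.paralog_ids.index("AMYm")][700:745]
        single_site = type(sites)(
            sites={736: sites.sites[736]},
            paralog_ids=sites.paralog_ids,
            proximal_count=0,
            distal_count=1,
            clusters=[(736,)],
        )
        counts = assign_reads([read], consensus, single_site)
        assert counts.assigned_total == 0 and counts.unassigned == 1

    def test_mixture_recovery(self):
        """Error-free reads from a (0.6, 0.3, 0.1) mixture are recovered
        within +-0.03 at n = 10,000."""
        rng = np.random.default_rng(1001)
        base = random_seq(rng, 250)
        paralogs = [mutate(rng, base, 0.02) for _ in range(3)]
        aln = ParalogAlignment(["p1", "p2", "p3"], paralogs)
        sites = find_diagnostic_sites(aln, max_cluster_span=150)
        consensus = consensus_from_alignment(aln)
        reads, _ = simulate_reads(paralogs, [0.6, 0.3, 0.1], 10000, 150, 0.0, seed=1)
        counts = assign_reads(reads, consensus, sites, max_mismatch_elsewhere=12)
        props = proportional_expression([counts.counts[p] for p in ["p1", "p2", "p3"]])
        np.testing.assert_allclose(props, [0.6, 0.3, 0.1], atol=0.03)

    def test_mixture_unbiased_across_error_rates(self):
        """Estimated proportions stay unbiased for error rates up to 1%
        (mean over seeds within Monte-Carlo error)."""
        for error_rate in (0.0, 0.01):
            estimates = []
            for seed in range(8):
                rng = np.random.default_rng(3000 + seed)
                base = random_seq(rng, 250)
                paralogs = [mutate(rng, base, 0.02) for _ in range(3)]
                aln = ParalogAlignment(["p1", "p2", "p3"], paralogs)
                sites = find_diagnostic_sites(aln, max_cluster_span=150)
                consensus = consensus_from_alignment(aln)
                reads, _ = simulate_reads(
                    paralogs, [0.6, 0.3, 0.1], 4000, 150, error_rate, seed=seed
                )
                counts = assign_reads(
                    reads, consensus, sites, max_mismatch_elsewhere=12
                )
                estimates.append(
                    proportional_expression(
                        [counts.counts[p] for p in ["p1", "p2", "p3"]]
                    )
                )
            mean_est = np.mean(estimates, axis=0)
            np.testing.assert_allclose(mean_est, [0.6, 0.3, 0.1], atol=0.03)


class TestCountPostprocessing:
    def test_filter_boundary_inclusive_at_ten(self):
        counts = pd.DataFrame(
            {"s1": [4, 5, 6], "s2": [5, 5, 5]}, index=["g1", "g2", "g3"]
        )  # row totals 9, 10, 11
        kept = filter_low_expression(counts, min_total=10)
        assert list(kept.index) == ["g2", "g3"]

    def test_filter_empty_matrix(self):
        empty = pd.DataFrame()
        assert filter_low_expression(empty).empty

    def test_filter_matches_row_sum_recomputation(self, rng):
        counts = pd.DataFrame(rng.integers(0, 8, size=(30, 4)))
        kept = filter_low_expression(counts, min_total=10)
        expected = [i for i in counts.index if counts.loc[i].sum() >= 10]
        assert list(kept.index) == expected

    def test_size_factors_identical_samples(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        np.testing.assert_allclose(median_of_ratios_size_factors(counts), [1.0, 1.0])

    def test_size_factors_scale_equivariance(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        factors = median_of_ratios_size_factors(counts)
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0)

    def test_size_factors_hand_computation(self):
        counts = pd.DataFrame(
            {
                "s1": [100, 50, 20, 80, 0],
                "s2": [200, 100, 40, 160, 10],
                "s3": [50, 25, 10, 40, 5],
            },
            index=[f"g{i}" for i in range(5)],
        )
        # reference (genes with no zero): geometric means of g0..g3 rows
        sub = counts.iloc[:4].to_numpy(dtype=float)
        ref = np.exp(np.mean(np.log(sub), axis=1))
        expected = np.median(sub / ref[:, None], axis=0)
        np.testing.assert_allclose(median_of_ratios_size_factors(counts), expected)

    def test_size_factors_require_all_positive_gene(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(InvalidInputError):
            median_of_ratios_size_factors(counts)

    def test_single_sample_scaling_equivariance(self, rng):
        """Scaling one sample's counts by c scales its factor by c relative
        to the others (the geometric-mean reference absorbs an overall
        rescaling, so only factor ratios are identified)."""
        counts = pd.DataFrame(rng.integers(1, 100, size=(50, 3)), columns=list("abc"))
        base = median_of_ratios_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        got = median_of_ratios_size_factors(scaled)
        assert got["b"] / got["a"] == pytest.approx(3 * base["b"] / base["a"])
        assert got["c"] / got["a"] == pytest.approx(base["c"] / base["a"])

    def test_log2fc_equal_means(self):
        m = pd.DataFrame({"a1": [5.0], "a2": [7.0], "b1": [6.0], "b2": [6.0]})
        assert log2_fold_change(m, ["a1", "a2"], ["b1", "b2"]).iloc[0] == 0.0

    def test_log2fc_fourfold(self):
        m = pd.DataFrame({"a": [8.0], "b": [2.0]})
        assert log2_fold_change(m, ["a"], ["b"], prior=0.0).iloc[0] == pytest.approx(2.0)

    def test_log2fc_toy_table(self):
        m = pd.DataFrame(
            {"a1": [1.0, 4.0, 10.0], "a2": [3.0, 4.0, 20.0], "b1": [2.0, 1.0, 5.0]}
        )
        got = log2_fold_change(m, ["a1", "a2"], ["b1"], prior=0.5)
        expected = np.log2((m[["a1", "a2"]].mean(axis=1) + 0.5) / (m["b1"] + 0.5))
        np.testing.assert_allclose(got, expected)

    def test_log2fc_rejects_overlapping_groups(self):
        m = pd.DataFrame({"a": [1.0], "b": [1.0]})
        with pytest.raises(InvalidInputError):
            log2_fold_change(m, ["a"], ["a", "b"])

    def test_proportions(self, rng):
        np.testing.assert_allclose(proportional_expression([10, 10]), [0.5, 0.5])
        np.testing.assert_allclose(proportional_expression([7.0]), [1.0])
        v = rng.uniform(0.1, 5.0, size=6)
        assert proportional_expression(list(v)).sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(UndefinedValueError):
            proportional_expression([0.0, 0.0])
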