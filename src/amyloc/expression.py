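"""Paralog-specific expression from allele-diagnostic CDS polymorphisms.

Closely related paralogs differ at a handful of coding positions; a small
set of such sites whose joint allele pattern uniquely identifies every
paralog lets individual RNA-seq reads be assigned unambiguously to the
paralog they came from.  This module selects those diagnostic sites from a
paralog alignment, assigns reads at them, and provides the standard count
post-processing: a minimum-total-read filter, median-of-ratios size
factors, log2 fold changes, and proportional expression summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import normalize
from .errors import InvalidInputError, UndefinedValueError

logger = logging.getLogger(__name__)

DEFAULT_PER_HALF_QUOTA = 2
DEFAULT_MAX_MISMATCH_ELSEWHERE = 2
_SEED_LEN = 20


@dataclass
class ParalogAlignment:
    """A gapless-row alignment of paralog CDS sequences ('-' for gaps)."""

    paralog_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.paralog_ids) != len(self.rows):
            raise InvalidInputError("one row per paralog id is required")
        if len(set(self.paralog_ids)) != len(self.paralog_ids):
            raise InvalidInputError("paralog ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InvalidInputError("alignment rows must have equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]


@dataclass
class DiagnosticSiteSet:
    """Selected alignment columns with per-paralog alleles.

    ``sites`` maps column index → {paralog id: allele}; jointly the allele
    patterns identify every paralog uniquely.  ``clusters`` groups the
    columns into co-selected runs (the proximal pair, the distal pair, any
    refinement columns); a read is informative when it spans a whole
    cluster, which keeps the probability of being countable identical
    across paralogs.
    """

    sites: dict[int, dict[str, str]]
    paralog_ids: list[str]
    proximal_count: int
    distal_count: int
    clusters: list[tuple[int, ...]] = field(default_factory=list)

    def pattern(self, paralog: str) -> tuple[str, ...]:
        return tuple(self.sites[c][paralog] for c in sorted(self.sites))


@dataclass
class ParalogCounts:
    counts: dict[str, int]
    unassigned: int
    unplaced: int

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())


def _informative_columns(aln: ParalogAlignment) -> list[int]:
    cols = []
    for i in range(aln.length):
        col = aln.column(i)
        if "-" in col or "N" in col:
            continue
        if len(set(col)) >= 2:
            cols.append(i)
    return cols


def _patterns_unique(aln: ParalogAlignment, columns: list[int]) -> bool:
    pats = {tuple(r[c] for c in columns) for r in aln.rows}
    return len(pats) == len(aln.rows)


def find_diagnostic_sites(
    aln: ParalogAlignment,
    per_half_quota: int = DEFAULT_PER_HALF_QUOTA,
    max_cluster_span: int | None = None,
) -> DiagnosticSiteSet:
    """Select allele-diagnostic columns from a paralog alignment.

    Candidate columns are gap-free with ≥ 2 distinct alleles.  The
    ``per_half_quota`` 5'-most candidates in the proximal half and the
    quota 3'-most candidates in the distal half are taken first (mirroring
    the two-proximal + two-distal design); if the joint patterns do not yet
    distinguish every paralog, further candidates are added greedily by
    maximal partition refinement until they do.

    When ``max_cluster_span`` is set (typically the read length), each
    half's columns are constrained to lie within a window of that span so
    that a single read can cover the whole cluster; among windows achieving
    the best attainable discrimination, the most extreme one is used.
    """
    if len(aln.paralog_ids) < 2:
        raise InvalidInputError("at least two paralogs are required")
    candidates = _informative_columns(aln)
    if not candidates:
        raise UndefinedValueError(
            "no diagnostic sites: paralog sequences are identical"
        )
    half = aln.length / 2.0
    proximal = [c for c in candidates if c < half]
    distal = [c for c in candidates if c >= half]

    def grow_cluster(anchor: int, pool: list[int], quota: int) -> list[int]:
        """Greedy cluster from ``anchor``: partners maximize joint
        discrimination, ties broken toward the anchor."""
        chosen = [anchor]
        pool = [c for c in pool if c != anchor]
        if max_cluster_span is not None:
            pool = [c for c in pool if abs(c - anchor) < max_cluster_span]
        n_par = len(aln.paralog_ids)
        while pool and (
            len(chosen) < quota
            or len({tuple(r[c] for c in chosen) for r in aln.rows}) < n_par
        ):
            def gain(col: int) -> tuple[int, int]:
                trial = chosen + [col]
                n_pat = len({tuple(r[c] for c in trial) for r in aln.rows})
                return (n_pat, -abs(col - anchor))

            best = max(pool, key=gain)
            if len(chosen) >= quota and gain(best)[0] <= len(
                {tuple(r[c] for c in chosen) for r in aln.rows}
            ):
                break  # quota met and no column refines further
            chosen.append(best)
            pool.remove(best)
        return chosen

    def n_patterns(cols: list[int]) -> int:
        return len({tuple(r[c] for c in cols) for r in aln.rows})

    def select_half(cols: list[int], quota: int, extreme_first: bool) -> list[int]:
        """Pick ``quota`` columns from one half: anchors are tried in
        extreme-first order (5'-most in the proximal half, 3'-most in the
        distal half) and the first cluster attaining the half's best
        achievable discrimination wins, so the selection stays as extreme
        as the data allow (mirroring the tight proximal/distal site pairs
        of the design)."""
        if not cols:
            return []
        ordered = sorted(cols) if extreme_first else sorted(cols, reverse=True)
        clusters = [grow_cluster(a, cols, quota) for a in ordered]
        best_n = max(n_patterns(c) for c in clusters)
        return next(c for c in clusters if n_patterns(c) == best_n)

    proximal_cluster = select_half(proximal, per_half_quota, extreme_first=True)
    distal_cluster = select_half(distal, per_half_quota, extreme_first=False)
    clusters = [
        tuple(sorted(c)) for c in (proximal_cluster, distal_cluster) if c
    ]
    # prefer fully discriminating clusters for read counting: a cluster
    # whose patterns collide for some paralog pair can only produce biased
    # assignments, so it is dropped from the counting set when a fully
    # discriminating alternative exists
    full = [c for c in clusters if n_patterns(list(c)) == len(aln.paralog_ids)]
    if full:
        clusters = full
    chosen = sorted(set(proximal_cluster + distal_cluster))
    remaining = [c for c in candidates if c not in chosen]
    while not _patterns_unique(aln, chosen) and remaining:
        def n_classes(col: int) -> int:
            trial = chosen + [col]
            return len({tuple(r[c] for c in trial) for r in aln.rows})

        best = max(remaining, key=lambda c: (n_classes(c), -c))
        chosen.append(best)
        chosen.sort()
        clusters.append((best,))
        remaining.remove(best)
    if not _patterns_unique(aln, chosen):
        pats: dict[tuple[str, ...], list[str]] = {}
        for pid, row in zip(aln.paralog_ids, aln.rows):
            pats.setdefault(tuple(row[c] for c in chosen), []).append(pid)
        clashes = [ids for ids in pats.values() if len(ids) > 1]
        raise UndefinedValueError(
            f"paralogs cannot be uniquely identified: {clashes}"
        )
    sites = {
        c: dict(zip(aln.paralog_ids, aln.column(c))) for c in chosen
    }
    return DiagnosticSiteSet(
        sites=sites,
        paralog_ids=list(aln.paralog_ids),
        proximal_count=sum(1 for c in chosen if c < half),
        distal_count=sum(1 for c in chosen if c >= half),
        clusters=clusters,
    )


def consensus_from_alignment(aln: ParalogAlignment) -> str:
    """Column-majority consensus of the paralog alignment (ties resolved in
    favor of the first paralog carrying a majority base; gap columns yield
    N)."""
    out = []
    for i in range(aln.length):
        col = [c for c in aln.column(i) if c != "-"]
        if not col:
            out.append("N")
            continue
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        out.append(next(c for c in col if counts[c] == best))
    return "".join(out)


def _place_read(
    read: str, consensus: str, site_columns: set[int], max_mismatch: int
) -> int | None:
    """Exact-seed placement of a read on the consensus.

    Seeds of length 20 are tried from successive read offsets until one
    places the read with at most ``max_mismatch`` mismatches outside the
    diagnostic sites.  Returns the 0-based start, or None.
    """
    L = len(read)
    k = min(_SEED_LEN, L)
    best: tuple[int, int] | None = None  # (mismatches, start)
    tried: set[int] = set()
    for seed_off in range(0, L - k + 1, k):
        seed = read[seed_off : seed_off + k]
        start = consensus.find(seed)
        while start != -1:
            place = start - seed_off
            if place >= 0 and place + L <= len(consensus) and place not in tried:
                tried.add(place)
                mm = sum(
                    1
                    for i in range(L)
                    if read[i] != consensus[place + i]
                    and (place + i) not in site_columns
                )
                if mm <= max_mismatch and (best is None or mm < best[0]):
                    best = (mm, place)
            start = consensus.find(seed, start + 1)
        if best is not None and best[0] == 0:
            break
    return best[1] if best else None


def assign_reads(
    reads: list[str],
    consensus: str,
    sites: DiagnosticSiteSet,
    max_mismatch_elsewhere: int = DEFAULT_MAX_MISMATCH_ELSEWHERE,
) -> ParalogCounts:
    """Assign reads to paralogs by their alleles at the diagnostic sites.

    A read is placed on the consensus and its bases at the diagnostic
    sites of every fully covered site cluster are compared with each
    paralog's alleles; it is counted for the single paralog compatible at
    ALL those sites.  Reads covering no complete cluster, or compatible
    with zero or several paralogs, are left unassigned (never fractionally
    allocated); unplaceable reads are tallied separately.  Requiring full
    cluster coverage keeps the chance of a read being countable a function
    of position only, identical across paralogs, so assigned counts are an
    unbiased sample of the underlying mixture.
    """
    consensus = normalize(consensus)
    site_columns = set(sites.sites)
    if site_columns and max(site_columns) >= len(consensus):
        raise InvalidInputError(
            "diagnostic site columns exceed the consensus length"
        )
    clusters = sites.clusters or [tuple(sorted(site_columns))]
    counts = {pid: 0 for pid in sites.paralog_ids}
    unassigned = 0
    unplaced = 0
    for read in reads:
        read = normalize(read)
        place = _place_read(read, consensus, site_columns, max_mismatch_elsewhere)
        if place is None:
            unplaced += 1
            logger.debug("read failed placement on the consensus")
            continue
        covered: list[int] = []
        for cluster in clusters:
            if all(place <= c < place + len(read) for c in cluster):
                covered.extend(cluster)
        if not covered:
            unassigned += 1
            continue
        compatible = [
            pid
            for pid in sites.paralog_ids
            if all(read[c - place] == sites.sites[c][pid] for c in covered)
        ]
        if len(compatible) == 1:
            counts[compatible[0]] += 1
        else:
            unassigned += 1
    return ParalogCounts(counts=counts, unassigned=unassigned, unplaced=unplaced)


def filter_low_expression(
    counts: pd.DataFrame, min_total: int = 10
) -> pd.DataFrame:
    """Drop genes (rows) with fewer than ``min_total`` reads summed across
    samples; the boundary is inclusive (a row totalling exactly
    ``min_total`` is kept)."""
    if counts.empty:
        return counts.copy()
    if (counts.to_numpy() < 0).any():
        raise InvalidInputError("counts must be non-negative")
    return counts.loc[counts.sum(axis=1) >= min_total].copy()


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference for gene g is its geometric mean across samples over the
    genes with no zero count; sample j's factor is the median over those
    genes of counts_gj / reference_g.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise InvalidInputError(
            "no gene has all-positive counts; size factors are undefined"
        )
    sub = mat[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_fold_change(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior: float = 0.5,
) -> pd.Series:
    """Per-gene log2((mean_A + prior) / (mean_B + prior)) on normalized counts."""
    if not group_a or not group_b:
        raise InvalidInputError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InvalidInputError("groups must be disjoint")
    mean_a = normalized[group_a].mean(axis=1)
    mean_b = normalized[group_b].mean(axis=1)
    return np.log2((mean_a + prior) / (mean_b + prior)).rename("log2fc")


def proportional_expression(values: list[float]) -> np.ndarray:
    """Normalize non-negative per-paralog values to proportions summing to 1."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise InvalidInputError("values must be non-negative")
    total = v.sum()
    if total <= 0:
        raise UndefinedValueError("proportions undefined for an all-zero vector")
    return v / total
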