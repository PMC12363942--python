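"""Pairwise alignment primitives shared by the locus, orthology and
architecture modules.

Two entry points:

* :func:`global_alignment` — end-to-end alignment of two sequences with
  match/mismatch scoring (+1/−1 by default) and linear gap costs, used for
  orthology similarity and mosaic-breakpoint column comparison.  The dynamic
  programming itself is delegated to :class:`Bio.Align.PairwiseAligner`.
* :func:`seeded_local_hits` — a seed-and-extend local similarity search:
  exact k-mer seeds are clustered by diagonal and each cluster is extended
  with a banded local alignment.  This is the engine behind anchor and CDS
  mapping.

N bases never score as matches: the substitution matrix assigns N the
mismatch score against every base including N, so assembly gaps cannot
inflate identity.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import normalize, revcomp
from .errors import InvalidInputError

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0
DEFAULT_SEED_LENGTH = 15
_DIAGONAL_BAND = 16  # max diagonal drift merged into one seed cluster


def _substitution_matrix(match: float, mismatch: float):
    letters = "ACGTN"
    m = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            if a == b and a != "N":
                m[a, b] = match
            else:
                m[a, b] = mismatch
    return m


def _make_aligner(mode: str, match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(match, mismatch)
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


@dataclass(frozen=True)
class PairwiseResult:
    """A finished pairwise alignment in column form."""

    query_aligned: str
    target_aligned: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    score: float
    identity: float  # matching columns / total alignment columns
    matches: int
    columns: int


def _columns_from_alignment(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _summarize(alignment, query: str, target: str) -> PairwiseResult:
    qa, ta = _columns_from_alignment(alignment)
    matches = sum(
        1 for a, b in zip(qa, ta) if a == b and a != "-" and a != "N"
    )
    columns = len(qa)
    q_blocks, t_blocks = alignment.aligned
    if len(q_blocks):
        q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
        t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    else:  # no aligned columns at all
        q_iv = (0, 0)
        t_iv = (0, 0)
    return PairwiseResult(
        query_aligned=qa,
        target_aligned=ta,
        query_interval=q_iv,
        target_interval=t_iv,
        score=float(alignment.score),
        identity=matches / columns if columns else 0.0,
        matches=matches,
        columns=columns,
    )


def global_alignment(
    query: str,
    target: str,
    *,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> PairwiseResult:
    """End-to-end alignment of ``query`` against ``target``.

    Identity is computed over all alignment columns; gaps and N columns count
    as mismatches.
    """
    query = normalize(query)
    target = normalize(target)
    aligner = _make_aligner("global", match, mismatch, gap)
    alignment = aligner.align(query, target)[0]
    return _summarize(alignment, query, target)


def local_alignment(
    query: str,
    target: str,
    *,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> PairwiseResult:
    """Best local alignment of ``query`` against ``target``."""
    query = normalize(query)
    target = normalize(target)
    aligner = _make_aligner("local", match, mismatch, gap)
    alignment = aligner.align(query, target)[0]
    return _summarize(alignment, query, target)


@dataclass(frozen=True)
class LocalHit:
    """A local similarity hit of a query on one strand of a target.

    ``query_interval`` is given on the original (forward) query; for minus
    strand hits the reverse complement of the query was aligned to the
    forward target, and ``target_interval`` stays in forward target
    coordinates.
    """

    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str  # "+" or "-"
    identity: float
    score: float
    query_coverage: float


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _seed_diagonals(query: str, index: dict[str, list[int]], k: int) -> dict[int, list[tuple[int, int]]]:
    """Map diagonal (target_pos − query_pos) to seed placements."""
    diagonals: dict[int, list[tuple[int, int]]] = {}
    for qi in range(len(query) - k + 1):
        kmer = query[qi : qi + k]
        for ti in index.get(kmer, ()):
            diagonals.setdefault(ti - qi, []).append((qi, ti))
    return diagonals


def _cluster_diagonals(diagonals: dict[int, list[tuple[int, int]]]) -> list[list[tuple[int, int]]]:
    clusters: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    last_diag: int | None = None
    for diag in sorted(diagonals):
        if last_diag is not None and diag - last_diag <= _DIAGONAL_BAND:
            current.extend(diagonals[diag])
        else:
            if current:
                clusters.append(current)
            current = list(diagonals[diag])
        last_diag = diag
    if current:
        clusters.append(current)
    return clusters


def seeded_local_hits(
    query: str,
    target: str,
    *,
    min_identity: float,
    min_query_cov: float,
    seed_length: int = DEFAULT_SEED_LENGTH,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
    search_both_strands: bool = True,
) -> list[LocalHit]:
    """Seed-and-extend local search of ``query`` against ``target``.

    Both strands are searched (the reverse complement of the query against
    the forward target).  Hits passing both the identity and query-coverage
    thresholds are returned sorted by descending score.
    """
    query = normalize(query)
    target = normalize(target)
    if len(query) < seed_length:
        raise InvalidInputError(
            f"query length {len(query)} is shorter than the seed length {seed_length}"
        )
    index = _kmer_index(target, seed_length)
    qlen = len(query)
    pad = max(32, qlen // 4)
    hits: list[LocalHit] = []
    strands = ["+", "-"] if search_both_strands else ["+"]
    for strand in strands:
        oriented = query if strand == "+" else revcomp(query)
        diagonals = _seed_diagonals(oriented, index, seed_length)
        for cluster in _cluster_diagonals(diagonals):
            t_positions = [ti - qi for qi, ti in cluster]
            lo = max(0, min(t_positions) - pad)
            hi = min(len(target), max(t_positions) + qlen + pad)
            window = target[lo:hi]
            res = local_alignment(oriented, window, match=match, mismatch=mismatch, gap=gap)
            if res.columns == 0:
                continue
            q_start, q_end = res.query_interval
            coverage = (q_end - q_start) / qlen
            if res.identity < min_identity or coverage < min_query_cov:
                continue
            t_iv = (lo + res.target_interval[0], lo + res.target_interval[1])
            if strand == "-":
                q_iv = (qlen - q_end, qlen - q_start)
            else:
                q_iv = (q_start, q_end)
            hits.append(
                LocalHit(
                    query_interval=q_iv,
                    target_interval=t_iv,
                    strand=strand,
                    identity=res.identity,
                    score=res.score,
                    query_coverage=coverage,
                )
            )
    hits = _deduplicate_hits(hits)
    hits.sort(key=lambda h: (-h.score, h.target_interval))
    return hits


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _deduplicate_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Collapse hits on the same strand whose target intervals overlap
    substantially, keeping the higher-scoring one."""
    kept: list[LocalHit] = []
    for hit in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for other in kept:
            if other.strand != hit.strand:
                continue
            ov = _overlap(other.target_interval, hit.target_interval)
            shorter = min(
                hit.target_interval[1] - hit.target_interval[0],
                other.target_interval[1] - other.target_interval[0],
            )
            if shorter and ov / shorter > 0.5:
                redundant = True
                break
        if not redundant:
            kept.append(hit)
    return kept
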