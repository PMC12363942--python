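"""Anchor-based locus extraction and gene-copy counting.

The locus of interest (e.g. the amylase cluster) is delimited by two
flanking, copy-number-stable anchor sequences.  Both anchors are searched
against every contig of an assembly; where the best pair of hits co-locates
on a single contig with consistent orientation, the intervening sequence —
anchor to anchor, outer edges inclusive — is extracted and reverse
complemented when on the minus strand so that the 5' anchor always leads.
Gene copies are then counted by mapping CDS queries onto the extracted
locus as contiguous high-identity placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import align
from ._seq import normalize, revcomp
from .errors import InvalidInputError, InvalidStateError

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_QUERY_COV = 0.8
#: fraction of the shorter placement that two gene-copy placements may share
#: before the lower-scoring one is dropped (tandem copies may share a short
#: tail, so a strict no-overlap rule would undercount)
DEFAULT_MAX_PLACEMENT_OVERLAP = 0.1


@dataclass(frozen=True)
class Contig:
    """A named assembly sequence restricted to the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise InvalidInputError("contig id must be non-empty")
        object.__setattr__(self, "sequence", normalize(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentBlock:
    """One local similarity hit of a query on a target contig."""

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str
    identity: float
    score: float

    def __post_init__(self):
        for iv in (self.query_interval, self.target_interval):
            if not iv[0] < iv[1]:
                raise InvalidInputError(f"degenerate interval {iv}")
        if not 0.0 <= self.identity <= 1.0:
            raise InvalidInputError(f"identity {self.identity} outside [0, 1]")
        if self.strand not in "+-":
            raise InvalidInputError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class LocusRecord:
    """An extracted locus: strand-normalized sequence plus its provenance.

    ``status`` is ``contiguous`` when both anchors mapped to one contig,
    ``fragmented`` when they mapped to different contigs (or with
    inconsistent orientation), and ``absent`` when either anchor found no
    hit.  Only contiguous records carry sequence.
    """

    species: str
    contig_id: str
    interval: tuple[int, int]
    strand: str
    sequence: str
    status: str

    def __post_init__(self):
        if self.status == "contiguous":
            if len(self.sequence) != self.interval[1] - self.interval[0]:
                raise InvalidInputError("sequence length does not match interval")
        elif self.status in ("fragmented", "absent"):
            if self.sequence:
                raise InvalidInputError(f"{self.status} locus must carry no sequence")
        else:
            raise InvalidInputError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class GeneCopy:
    """A gene-copy placement within a locus (locus-relative coordinates)."""

    id: str
    locus_interval: tuple[int, int]
    strand: str
    identity: float
    source_query: str


def find_anchor_hits(
    anchor: str,
    contigs: list[Contig],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    *,
    anchor_id: str = "anchor",
    seed_length: int = align.DEFAULT_SEED_LENGTH,
) -> list[AlignmentBlock]:
    """Search ``anchor`` against every contig on both strands.

    Returns blocks with identity ≥ ``min_identity`` and query coverage ≥
    ``min_query_cov``, sorted by descending score.
    """
    if not contigs:
        raise InvalidInputError("empty contig set")
    anchor = normalize(anchor)
    if len(anchor) < seed_length:
        raise InvalidInputError(
            f"anchor length {len(anchor)} shorter than seed length {seed_length}"
        )
    blocks: list[AlignmentBlock] = []
    for contig in contigs:
        for hit in align.seeded_local_hits(
            anchor,
            contig.sequence,
            min_identity=min_identity,
            min_query_cov=min_query_cov,
            seed_length=seed_length,
        ):
            blocks.append(
                AlignmentBlock(
                    query_id=anchor_id,
                    target_id=contig.id,
                    query_interval=hit.query_interval,
                    target_interval=hit.target_interval,
                    strand=hit.strand,
                    identity=hit.identity,
                    score=hit.score,
                )
            )
    blocks.sort(key=lambda b: (-b.score, b.target_id, b.target_interval))
    return blocks


def extract_locus(
    hits5: list[AlignmentBlock],
    hits3: list[AlignmentBlock],
    contigs: list[Contig],
    *,
    species: str = "",
) -> LocusRecord:
    """Extract the locus between the best consistent 5'/3' anchor hit pair.

    A pair is consistent when both hits lie on the same contig and strand
    with the 5' anchor upstream of the 3' anchor in transcription
    orientation.  Among consistent pairs the one maximizing summed score is
    chosen, ties broken by shortest locus.  The returned sequence runs from
    the outer edge of the 5' anchor to the outer edge of the 3' anchor and
    is reverse complemented for minus-strand loci so the 5' anchor leads.
    """
    if not hits5 or not hits3:
        return LocusRecord(species, "", (0, 0), "+", "", "absent")
    by_id = {c.id: c for c in contigs}
    best: tuple[float, int, AlignmentBlock, AlignmentBlock] | None = None
    shared_contig = False
    for h5 in hits5:
        for h3 in hits3:
            if h5.target_id != h3.target_id:
                continue
            shared_contig = True
            if h5.strand != h3.strand:
                continue
            if h5.strand == "+":
                if h5.target_interval[0] >= h3.target_interval[0]:
                    continue
                iv = (h5.target_interval[0], h3.target_interval[1])
            else:
                if h3.target_interval[0] >= h5.target_interval[0]:
                    continue
                iv = (h3.target_interval[0], h5.target_interval[1])
            length = iv[1] - iv[0]
            key = (h5.score + h3.score, -length)
            if best is None or key > (best[0], -best[1]):
                best = (key[0], length, h5, h3)
    if best is None:
        if shared_contig:
            logger.warning(
                "anchor hits share a contig but have inconsistent orientation "
                "or ordering; flagging locus as fragmented"
            )
        else:
            logger.warning("anchors map to different contigs; locus fragmented")
        return LocusRecord(species, "", (0, 0), "+", "", "fragmented")
    _, _, h5, h3 = best
    contig = by_id[h5.target_id]
    strand = h5.strand
    if strand == "+":
        iv = (h5.target_interval[0], h3.target_interval[1])
        seq = contig.sequence[iv[0] : iv[1]]
    else:
        iv = (h3.target_interval[0], h5.target_interval[1])
        seq = revcomp(contig.sequence[iv[0] : iv[1]])
    return LocusRecord(species, contig.id, iv, strand, seq, "contiguous")


def map_gene_copies(
    locus: LocusRecord,
    cds_queries: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_cov: float = DEFAULT_MIN_QUERY_COV,
    *,
    max_overlap_frac: float = DEFAULT_MAX_PLACEMENT_OVERLAP,
) -> list[GeneCopy]:
    """Count gene copies in a contiguous locus by CDS placement.

    All CDS queries are mapped with the seed-and-extend search; candidate
    placements are then selected greedily by descending score, discarding
    any placement overlapping an already-kept one by more than
    ``max_overlap_frac`` of the shorter placement.  The number of returned
    records is the reported copy number.
    """
    if locus.status != "contiguous":
        raise InvalidStateError(
            f"gene copies can only be mapped on a contiguous locus (status={locus.status})"
        )
    candidates: list[tuple[float, tuple[int, int], str, float, str]] = []
    target = Contig("locus", locus.sequence)
    for query_id, cds in cds_queries.items():
        for hit in align.seeded_local_hits(
            normalize(cds),
            target.sequence,
            min_identity=min_identity,
            min_query_cov=min_cov,
        ):
            candidates.append(
                (hit.score, hit.target_interval, hit.strand, hit.identity, query_id)
            )
    candidates.sort(key=lambda c: (-c[0], c[1]))
    kept: list[tuple[float, tuple[int, int], str, float, str]] = []
    for cand in candidates:
        ok = True
        for other in kept:
            ov = align._overlap(cand[1], other[1])
            shorter = min(cand[1][1] - cand[1][0], other[1][1] - other[1][0])
            if shorter and ov / shorter > max_overlap_frac:
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda c: c[1])
    return [
        GeneCopy(
            id=f"{query_id}.copy{i + 1}",
            locus_interval=iv,
            strand=strand,
            identity=identity,
            source_query=query_id,
        )
        for i, (score, iv, strand, identity, query_id) in enumerate(kept)
    ]


def write_locus_outputs(locus: LocusRecord, out_prefix: str) -> None:
    """Emit a locus as wrapped FASTA plus a BED line of its interval."""
    from ._seq import wrap_fasta

    with open(f"{out_prefix}.fa", "w") as fh:
        if locus.status == "contiguous":
            header = f"{locus.species or 'locus'} {locus.contig_id}:{locus.interval[0]}-{locus.interval[1]}({locus.strand})"
            fh.write(wrap_fasta(header, locus.sequence))
    with open(f"{out_prefix}.bed", "w") as fh:
        if locus.status == "contiguous":
            fh.write(
                f"{locus.contig_id}\t{locus.interval[0]}\t{locus.interval[1]}\t"
                f"{locus.species or 'locus'}\t0\t{locus.strand}\n"
            )
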