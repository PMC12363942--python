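"""Duplicon segmentation, NAHR mosaic-breakpoint calling, and
duplication-age bracketing on dated trees.

A locus is partitioned into duplicon segments (one gene copy each,
boundaries at inter-gene gap midpoints).  A derived segment produced by
non-allelic homologous recombination (NAHR) is a mosaic: its 5' part
matches one donor duplicon and its 3' part another, with a crossover
interval in between within which the donors are locally identical and the
breakpoint cannot be placed.  Presence/absence of a duplicate across the
tips of a dated ultrametric tree brackets the duplication age between the
carriers' MRCA and their split from the nearest non-carrier lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy

from . import align
from ._seq import normalize
from .errors import InvalidInputError
from .locus_extraction import GeneCopy, LocusRecord

DEFAULT_MIN_SUPPORT = 0.8
DEFAULT_MAX_CROSSOVER_FRAC = 0.2
ULTRAMETRIC_TOL = 1e-6


@dataclass(frozen=True)
class DupliconSegment:
    interval: tuple[int, int]
    member_gene: str | None
    label: str


@dataclass
class MosaicCall:
    derived: str
    donor5: str
    donor3: str
    crossover_interval: tuple[int, int]
    support5: float
    support3: float
    mechanism: str  # NAHR | unresolved
    masked_n_positions: int = 0


def segment_locus(
    locus: LocusRecord, gene_copies: list[GeneCopy]
) -> list[DupliconSegment]:
    """Tile the locus into one segment per gene copy plus flank segments.

    Internal boundaries sit at the midpoints of inter-gene gaps; the 5' and
    3' flanks (before the first gene start / after the last gene end) form
    their own segments when non-empty.
    """
    if not gene_copies:
        raise InvalidInputError("at least one gene copy is required")
    copies = sorted(gene_copies, key=lambda g: g.locus_interval)
    for prev, cur in zip(copies, copies[1:]):
        if cur.locus_interval[0] < prev.locus_interval[1]:
            raise InvalidInputError(
                f"overlapping gene copies {prev.id} and {cur.id}"
            )
    locus_len = len(locus.sequence) if locus.sequence else locus.interval[1] - locus.interval[0]
    boundaries = [copies[0].locus_interval[0]]
    for prev, cur in zip(copies, copies[1:]):
        boundaries.append((prev.locus_interval[1] + cur.locus_interval[0]) // 2)
    boundaries.append(copies[-1].locus_interval[1])

    segments: list[DupliconSegment] = []
    if boundaries[0] > 0:
        segments.append(DupliconSegment((0, boundaries[0]), None, "flank5"))
    for i, copy in enumerate(copies):
        start = boundaries[i]
        end = boundaries[i + 1]
        segments.append(DupliconSegment((start, end), copy.id, f"segment{i + 1}"))
    if boundaries[-1] < locus_len:
        segments.append(DupliconSegment((boundaries[-1], locus_len), None, "flank3"))
    return segments


def _match_profile(derived: str, donor: str) -> list[tuple[int, str]]:
    """Per-derived-position aligned donor character ('-' for a gap)."""
    res = align.global_alignment(derived, donor)
    profile: list[tuple[int, str]] = []
    di = 0
    for dc, oc in zip(res.query_aligned, res.target_aligned):
        if dc != "-":
            profile.append((di, oc))
            di += 1
    return profile


def call_mosaic_breakpoints(
    derived: str,
    donor_a: str,
    donor_b: str,
    *,
    min_support: float = DEFAULT_MIN_SUPPORT,
    labels: tuple[str, str, str] = ("derived", "donorA", "donorB"),
) -> MosaicCall:
    """Locate the 5'-donorA / 3'-donorB crossover in a putative mosaic.

    The derived sequence is globally aligned to each donor; for every split
    position k the objective matches(derived[0:k], donorA) +
    matches(derived[k:], donorB) is evaluated via prefix sums, and the
    crossover interval is the plateau of split positions attaining the
    optimum (within it the two donors agree with each other, so the
    breakpoint is not localizable).  Support values are the identities of
    the two flanks outside the plateau; both must reach ``min_support`` for
    a NAHR-compatible call.  N positions in the derived sequence are masked
    from all counts.
    """
    derived = normalize(derived)
    L = len(derived)
    prof_a = _match_profile(derived, donor_a)
    prof_b = _match_profile(derived, donor_b)
    match_a = [0] * L
    match_b = [0] * L
    masked = [derived[i] == "N" for i in range(L)]
    for di, oc in prof_a:
        if not masked[di] and oc == derived[di]:
            match_a[di] = 1
    for di, oc in prof_b:
        if not masked[di] and oc == derived[di]:
            match_b[di] = 1

    # prefix sums: score(k) = sum(match_a[:k]) + sum(match_b[k:])
    pa = [0] * (L + 1)
    pb = [0] * (L + 1)
    for i in range(L):
        pa[i + 1] = pa[i] + match_a[i]
        pb[i + 1] = pb[i] + match_b[i]
    total_b = pb[L]
    scores = [pa[k] + (total_b - pb[k]) for k in range(L + 1)]
    best = max(scores)
    opt = [k for k in range(L + 1) if scores[k] == best]
    # plateau containing the first optimum (optima are contiguous whenever
    # the donors agree locally; take the maximal contiguous run)
    lo = opt[0]
    hi = lo
    for k in opt[1:]:
        if k == hi + 1:
            hi = k
        else:
            break
    n_masked = sum(masked)

    def _identity(matches: int, span: int) -> float:
        return matches / span if span > 0 else 0.0

    unmasked5 = lo - sum(masked[:lo])
    unmasked3 = (L - hi) - sum(masked[hi:])
    support5 = _identity(pa[lo], unmasked5)
    support3 = _identity(total_b - pb[hi], unmasked3)
    localized = lo > 0 and hi < L
    mechanism = (
        "NAHR"
        if localized and support5 >= min_support and support3 >= min_support
        else "unresolved"
    )
    return MosaicCall(
        derived=labels[0],
        donor5=labels[1],
        donor3=labels[2],
        crossover_interval=(lo, hi),
        support5=support5,
        support3=support3,
        mechanism=mechanism,
        masked_n_positions=n_masked,
    )


def classify_mechanism(
    call: MosaicCall,
    derived_length: int,
    *,
    flanks_homologous_direct: bool,
    min_support: float = DEFAULT_MIN_SUPPORT,
    max_crossover_frac: float = DEFAULT_MAX_CROSSOVER_FRAC,
) -> str:
    """Final NAHR classification of a mosaic call in its segment context.

    NAHR requires (i) the derived segment to sit between homologous donor
    segments in direct orientation, and (ii) mosaic support ≥ ``min_support``
    on both sides with a crossover localized to at most
    ``max_crossover_frac`` of the derived segment.
    """
    if not flanks_homologous_direct:
        return "unresolved"
    width = call.crossover_interval[1] - call.crossover_interval[0]
    if width > max_crossover_frac * derived_length:
        return "unresolved"
    if call.support5 < min_support or call.support3 < min_support:
        return "unresolved"
    return "NAHR"


@dataclass
class DatedTree:
    """A rooted ultrametric tree with node ages in million years.

    Tip ages are 0; every internal node's age is the (equal) distance to
    each of its descendant tips.
    """

    tree: dendropy.Tree
    tip_labels: frozenset[str] = field(init=False)

    def __post_init__(self):
        depths = {}
        self._age = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        tip_depths = [depths[t] for t in self.tree.leaf_node_iter()]
        self.height = max(tip_depths)
        span = self.height - min(tip_depths)
        if self.height > 0 and span > ULTRAMETRIC_TOL * max(1.0, self.height):
            raise InvalidInputError(
                f"tree is not ultrametric (root-to-tip span {span:g})"
            )
        for node in self.tree.preorder_node_iter():
            self._age[node] = self.height - depths[node]
        self.tip_labels = frozenset(
            t.taxon.label for t in self.tree.leaf_node_iter()
        )

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
        return cls(tree)

    def node_age(self, node) -> float:
        return self._age[node]

    def mrca(self, labels: set[str]):
        return self.tree.mrca(taxon_labels=sorted(labels))


@dataclass(frozen=True)
class AgeBracket:
    lower_mya: float
    upper_mya: float  # math.inf when every tip carries the duplicate
    carriers: frozenset[str]
    bounding_noncarrier: str | None


def bracket_duplication_age(tree: DatedTree, carriers: set[str]) -> AgeBracket:
    """Bracket a duplication's age from carrier/non-carrier tips.

    Lower bound: age of the carriers' MRCA (0 for a single carrier tip).
    Upper bound: age of the split between the carrier clade and its closest
    non-carrier lineage (+inf when all tips carry the duplicate).  Carriers
    must be monophyletic — a duplicate is assumed present in all
    descendants of its origin, secondary loss is not modeled.
    """
    carriers = set(carriers)
    if not carriers:
        raise InvalidInputError("carrier set must be non-empty")
    unknown = carriers - tree.tip_labels
    if unknown:
        raise InvalidInputError(f"carriers not in tree: {sorted(unknown)}")
    if carriers == tree.tip_labels:
        return AgeBracket(tree.height, math.inf, frozenset(carriers), None)
    if len(carriers) == 1:
        leaf = next(
            t for t in tree.tree.leaf_node_iter() if t.taxon.label in carriers
        )
        mrca_node = leaf
        lower = 0.0
    else:
        mrca_node = tree.mrca(carriers)
        clade_tips = {t.taxon.label for t in mrca_node.leaf_iter()}
        extra = clade_tips - carriers
        if extra:
            raise InvalidInputError(
                "carriers are not monophyletic; non-carrier tips inside the "
                f"carrier clade: {sorted(extra)}"
            )
        lower = tree.node_age(mrca_node)
    parent = mrca_node.parent_node
    upper = tree.node_age(parent)
    sibling_tips: list[str] = []
    for child in parent.child_nodes():
        if child is not mrca_node:
            sibling_tips.extend(t.taxon.label for t in child.leaf_iter())
    bounding = ",".join(sorted(sibling_tips)) if sibling_tips else None
    return AgeBracket(lower, upper, frozenset(carriers), bounding)


def write_segments_bed(segments: list[DupliconSegment], locus_name: str, path: str) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{locus_name}\t{seg.interval[0]}\t{seg.interval[1]}\t{seg.label}\n")
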