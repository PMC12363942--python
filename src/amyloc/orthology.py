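"""Reciprocal-best-hit orthology and duplication polarity.

Gene sets from two species are compared all-vs-all; mutual top hits define
one-to-one orthologs, while one-to-many / many-to-one patterns — a single
gene in one species that is the top hit of several genes in the other,
which in turn tops at least one of them — indicate a lineage-specific
duplication in the "many" lineage.  Ties for the top hit are never broken
arbitrarily: the affected genes come back as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import align
from .errors import InvalidInputError


@dataclass
class SimilarityMatrix:
    """Dense all-vs-all alignment scores and identities between two gene sets."""

    genes_a: list[str]
    genes_b: list[str]
    scores: np.ndarray  # shape (|A|, |B|)
    identities: np.ndarray

    def __post_init__(self):
        expected = (len(self.genes_a), len(self.genes_b))
        if self.scores.shape != expected or self.identities.shape != expected:
            raise InvalidInputError("matrix dimensions do not match gene id lists")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError("scores must be finite")


@dataclass
class OrthologyCall:
    relation: str  # one_to_one | one_to_many | many_to_one | unresolved
    a_members: list[str]
    b_members: list[str]
    duplicated_lineage: str = "none"  # A | B | none | ambiguous


def all_vs_all_similarity(
    genes_a: dict[str, str], genes_b: dict[str, str]
) -> SimilarityMatrix:
    """Score every (a, b) pair with a global alignment (+1/−1, gap −2)."""
    if not genes_a or not genes_b:
        raise InvalidInputError("gene sets must be non-empty")
    ids_a = list(genes_a)
    ids_b = list(genes_b)
    scores = np.zeros((len(ids_a), len(ids_b)))
    idents = np.zeros_like(scores)
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            res = align.global_alignment(genes_a[a], genes_b[b])
            scores[i, j] = res.score
            idents[i, j] = res.identity
    return SimilarityMatrix(ids_a, ids_b, scores, idents)


def _top_set(row: np.ndarray) -> frozenset[int]:
    """Indices attaining the row maximum (a singleton unless tied)."""
    return frozenset(np.flatnonzero(row == row.max()).tolist())


def reciprocal_best_hits(matrix: SimilarityMatrix) -> list[OrthologyCall]:
    """Partition genes into one_to_one / one_to_many / many_to_one /
    unresolved calls from the score matrix.

    Rules:

    1. ``one_to_many`` (duplication in B): gene a together with the group
       G = {b : b's top hit is uniquely a} when |G| ≥ 2 and every top hit
       of a lies in G.  A tie among members of the same group is harmless
       (two fresh paralogs are often equidistant from their ortholog);
       only a tie reaching outside the group voids the pattern.
    2. ``many_to_one`` (duplication in A): the mirror pattern.
    3. A gene claimed by candidate calls in both directions is genuinely
       ambiguous and comes back unresolved, as do its partners.
    4. Remaining pairs that are each other's unique top hit are
       one_to_one; any other tie for a top hit, and anything left over,
       is unresolved (never an arbitrary assignment).
    """
    S = matrix.scores
    na, nb = S.shape
    top_a = [_top_set(S[i, :]) for i in range(na)]  # a -> indices in B
    top_b = [_top_set(S[:, j]) for j in range(nb)]  # b -> indices in A

    # candidate many-patterns in each direction
    one_to_many: list[tuple[int, list[int]]] = []  # (a, [b...]) duplication in B
    for i in range(na):
        group = [j for j in range(nb) if top_b[j] == {i}]
        if len(group) >= 2 and top_a[i] <= set(group):
            one_to_many.append((i, group))
    many_to_one: list[tuple[int, list[int]]] = []  # (b, [a...]) duplication in A
    for j in range(nb):
        group = [i for i in range(na) if top_a[i] == {j}]
        if len(group) >= 2 and top_b[j] <= set(group):
            many_to_one.append((j, group))

    # genes claimed by both pattern directions are ambiguous
    claimed_a_o2m = {i for i, _ in one_to_many}
    claimed_b_o2m = {j for _, g in one_to_many for j in g}
    claimed_a_m2o = {i for _, g in many_to_one for i in g}
    claimed_b_m2o = {j for j, _ in many_to_one}
    conflict_a = claimed_a_o2m & claimed_a_m2o
    conflict_b = claimed_b_o2m & claimed_b_m2o

    calls: list[OrthologyCall] = []
    used_a: set[int] = set()
    used_b: set[int] = set()

    def conflicted(a_idx: int | None = None, b_group=(), a_group=(), b_idx=None) -> bool:
        if a_idx is not None and a_idx in conflict_a:
            return True
        if b_idx is not None and b_idx in conflict_b:
            return True
        return any(j in conflict_b for j in b_group) or any(i in conflict_a for i in a_group)

    for i, group in one_to_many:
        if conflicted(a_idx=i, b_group=group):
            continue
        calls.append(
            OrthologyCall(
                "one_to_many",
                [matrix.genes_a[i]],
                [matrix.genes_b[j] for j in sorted(group)],
                duplicated_lineage="B",
            )
        )
        used_a.add(i)
        used_b.update(group)
    for j, group in many_to_one:
        if conflicted(b_idx=j, a_group=group):
            continue
        calls.append(
            OrthologyCall(
                "many_to_one",
                [matrix.genes_a[i] for i in sorted(group)],
                [matrix.genes_b[j]],
                duplicated_lineage="A",
            )
        )
        used_b.add(j)
        used_a.update(group)

    for i in range(na):
        if i in used_a or len(top_a[i]) != 1:
            continue
        j = next(iter(top_a[i]))
        if j not in used_b and top_b[j] == {i}:
            calls.append(
                OrthologyCall(
                    "one_to_one",
                    [matrix.genes_a[i]],
                    [matrix.genes_b[j]],
                    duplicated_lineage="none",
                )
            )
            used_a.add(i)
            used_b.add(j)

    for i in range(na):
        if i not in used_a:
            calls.append(
                OrthologyCall("unresolved", [matrix.genes_a[i]], [], "ambiguous")
            )
    for j in range(nb):
        if j not in used_b:
            calls.append(
                OrthologyCall("unresolved", [], [matrix.genes_b[j]], "ambiguous")
            )
    return calls


def infer_duplication_polarity(calls: list[OrthologyCall]) -> list[str]:
    """Label, per call, which lineage duplicated (the "many" side)."""
    labels = []
    for call in calls:
        if call.relation == "one_to_many":
            label = "B"
        elif call.relation == "many_to_one":
            label = "A"
        elif call.relation == "one_to_one":
            label = "none"
        else:
            label = "ambiguous"
        call.duplicated_lineage = label
        labels.append(label)
    return labels


def write_orthology_table(calls: list[OrthologyCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("relation\ta_members\tb_members\tduplicated_lineage\n")
        for c in calls:
            fh.write(
                f"{c.relation}\t{','.join(c.a_members) or '.'}\t"
                f"{','.join(c.b_members) or '.'}\t{c.duplicated_lineage}\n"
            )
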