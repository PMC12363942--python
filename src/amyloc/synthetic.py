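"""Seeded generators for synthetic inputs with known ground truth.

Each generator is a pure function of its parameters and seed and returns
the generated data together with a :class:`SimulationTruth` record, so
every downstream stage can be validated against construction-time truth:

* :func:`simulate_locus_nahr` — an anchored multi-gene locus in which NAHR
  events insert mosaic (5'-donor / 3'-donor) gene blocks, optionally with
  an LTR-like cassette at the event junction;
* :func:`simulate_bm_traits` — correlated tip traits under Brownian motion
  with Pagel's λ structure, for phylogenetic regression recovery;
* :func:`simulate_reads` — reads drawn from a paralog mixture with uniform
  substitution errors, for diagnostic-site assignment;
* :func:`simulate_counts` — negative-binomial count matrices with known
  size factors, for median-of-ratios recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .architecture import DatedTree
from .errors import InvalidInputError

BASES = "ACGT"
ANCHOR_LEN = 300
LTR_UNIT_LEN = 400
LTR_REPEAT_LEN = 50


@dataclass
class SimulationTruth:
    scenario: str
    seed: int
    parameters: dict[str, Any]
    records: dict[str, Any] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def _ltr_cassette(rng: np.random.Generator) -> str:
    """A minimal LTR-like cassette: 50 bp terminal direct repeats flanking
    a 400 bp internal body (synthetic, no real element sequence)."""
    repeat = _random_seq(rng, LTR_REPEAT_LEN)
    body = _random_seq(rng, LTR_UNIT_LEN)
    return repeat + body + repeat


def simulate_locus_nahr(
    seed: int,
    n_initial_genes: int = 2,
    gene_len: int = 2000,
    spacer_len: int = 800,
    divergence: float = 0.02,
    events: list[tuple[int, int, int]] | None = None,
    ltr_at_junction: bool = False,
    flank_len: int = 500,
    derived_private_divergence: float = 0.005,
) -> tuple[list, SimulationTruth]:
    """Build an anchored locus and apply NAHR duplication events.

    The ancestral locus is anchor5 — gene blocks separated by spacers —
    anchor3; paralogs diverge from a common gene sequence by marker SNVs at
    rate ``divergence``.  Each event ``(donor5, donor3, crossover_pos)``
    (donor indices into the current gene-block list, crossover position
    within the gene block) inserts a mosaic block made of donor5's prefix
    and donor3's suffix immediately after the donor5 block.  Returns a
    single-contig assembly plus the truth record (anchors, block
    coordinates, breakpoints, copy number, paralog sequences).
    """
    from .locus_extraction import Contig

    rng = np.random.default_rng(seed)
    if n_initial_genes < 1:
        raise InvalidInputError("need at least one initial gene")
    base_gene = _random_seq(rng, gene_len)
    blocks: list[tuple[str, str]] = []  # (label, sequence)
    for i in range(n_initial_genes):
        blocks.append((f"gene{i + 1}", _mutate(rng, base_gene, divergence)))

    event_truth = []
    for k, (d5, d3, pos) in enumerate(events or []):
        if not (0 <= d5 < len(blocks) and 0 <= d3 < len(blocks)) or d5 == d3:
            raise InvalidInputError(f"event {k}: invalid donor indices ({d5}, {d3})")
        if not 0 < pos < gene_len:
            raise InvalidInputError(
                f"event {k}: crossover {pos} outside the homologous span (0, {gene_len})"
            )
        donor5_label = blocks[d5][0]
        donor3_label = blocks[d3][0]
        mosaic = blocks[d5][1][:pos] + blocks[d3][1][pos:]
        if derived_private_divergence > 0:
            # post-duplication private SNVs: real derived copies are not
            # exact donor chimeras
            mosaic = _mutate(rng, mosaic, derived_private_divergence)
        label = f"mosaic{k + 1}"
        blocks.insert(d5 + 1, (label, mosaic))
        event_truth.append(
            {
                "derived": label,
                "donor5": donor5_label,
                "donor3": donor3_label,
                "crossover": pos,
                "ltr": ltr_at_junction,
            }
        )

    anchor5 = _random_seq(rng, ANCHOR_LEN)
    anchor3 = _random_seq(rng, ANCHOR_LEN)
    parts: list[str] = [anchor5]
    coords: dict[str, tuple[int, int]] = {}
    pos_cursor = ANCHOR_LEN
    for i, (label, seq) in enumerate(blocks):
        spacer = _random_seq(rng, spacer_len)
        parts.append(spacer)
        pos_cursor += spacer_len
        if ltr_at_junction and label.startswith("mosaic"):
            cassette = _ltr_cassette(rng)
            parts.append(cassette)
            pos_cursor += len(cassette)
        coords[label] = (pos_cursor, pos_cursor + len(seq))
        parts.append(seq)
        pos_cursor += len(seq)
    parts.append(_random_seq(rng, spacer_len))
    pos_cursor += spacer_len
    parts.append(anchor3)
    pos_cursor += ANCHOR_LEN
    locus = "".join(parts)

    left_pad = _random_seq(rng, flank_len)
    right_pad = _random_seq(rng, flank_len)
    contig = Contig("sim_contig_1", left_pad + locus + right_pad)

    truth = SimulationTruth(
        scenario="locus_nahr",
        seed=seed,
        parameters={
            "n_initial_genes": n_initial_genes,
            "gene_len": gene_len,
            "spacer_len": spacer_len,
            "divergence": divergence,
            "ltr_at_junction": ltr_at_junction,
        },
        records={
            "anchor5": anchor5,
            "anchor3": anchor3,
            "copy_number": len(blocks),
            "block_order": [label for label, _ in blocks],
            "block_coords_in_locus": coords,
            "block_seqs": {label: seq for label, seq in blocks},
            "events": event_truth,
            "locus_interval_in_contig": (flank_len, flank_len + len(locus)),
        },
    )
    return [contig], truth


def simulate_ultrametric_tree(
    n_tips: int, seed: int, height: float = 1.0
) -> DatedTree:
    """A random ultrametric tree by coalescent-style pair merging.

    n − 1 node ages are drawn uniformly and rescaled so the root sits at
    ``height``; at each event two random lineages merge.
    """
    if n_tips < 2:
        raise InvalidInputError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(0.05, 1.0, size=n_tips - 1))
    ages = ages / ages[-1] * height
    lineages: list[tuple[str, float]] = [(f"t{i}", 0.0) for i in range(n_tips)]
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, aa), (nb, ab) = lineages[i], lineages[j]
        merged = f"({na}:{age - aa:.10g},{nb}:{age - ab:.10g})"
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append((merged, age))
    newick = lineages[0][0] + ";"
    return DatedTree.from_newick(newick)


def simulate_bm_traits(
    tree: DatedTree,
    lam: float,
    sigma2: float,
    intercept: float,
    slope: float,
    noise_sd: float,
    seed: int,
) -> tuple[dict[str, float], dict[str, float], SimulationTruth]:
    """Draw (x, y) tip traits with y = a + b·x + phylogenetic residual.

    x and the residual are multivariate normal with covariance σ²·C(λ);
    independent Gaussian noise of sd ``noise_sd`` is added to y.
    """
    from .te_landscape import _lambda_cov, phylogenetic_covariance

    if not 0.0 <= lam <= 1.0:
        raise InvalidInputError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tips = sorted(tree.tip_labels)
    C = phylogenetic_covariance(tree, tips)
    V = sigma2 * _lambda_cov(C, lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(tips)))
    xv = L @ rng.standard_normal(len(tips))
    resid = L @ rng.standard_normal(len(tips))
    yv = intercept + slope * xv + resid + noise_sd * rng.standard_normal(len(tips))
    x = dict(zip(tips, map(float, xv)))
    y = dict(zip(tips, map(float, yv)))
    truth = SimulationTruth(
        scenario="bm_traits",
        seed=seed,
        parameters={
            "lambda": lam,
            "sigma2": sigma2,
            "intercept": intercept,
            "slope": slope,
            "noise_sd": noise_sd,
        },
        records={"lambda": lam, "slope": slope},
    )
    return x, y, truth


def simulate_reads(
    paralog_seqs: list[str],
    mixture: list[float],
    n_reads: int,
    read_len: int,
    error_rate: float,
    seed: int,
) -> tuple[list[str], SimulationTruth]:
    """Draw reads from a paralog mixture with substitution errors.

    Each read comes from a mixture-chosen paralog at a uniform start
    position; the truth records the source paralog of every read.
    """
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise InvalidInputError("mixture weights must sum to 1")
    if len(mixture) != len(paralog_seqs):
        raise InvalidInputError("one mixture weight per paralog is required")
    min_len = min(len(s) for s in paralog_seqs)
    if read_len > min_len:
        raise InvalidInputError(
            f"read length {read_len} exceeds the shortest paralog ({min_len})"
        )
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(paralog_seqs), size=n_reads, p=mixture)
    reads: list[str] = []
    for src in sources:
        seq = paralog_seqs[src]
        start = int(rng.integers(0, len(seq) - read_len + 1))
        read = seq[start : start + read_len]
        if error_rate > 0:
            read = _mutate(rng, read, error_rate)
        reads.append(read)
    truth = SimulationTruth(
        scenario="reads",
        seed=seed,
        parameters={
            "mixture": list(mixture),
            "n_reads": n_reads,
            "read_len": read_len,
            "error_rate": error_rate,
        },
        records={"source_per_read": sources.tolist()},
    )
    return reads, truth


def simulate_counts(
    n_genes: int,
    samples: list[str],
    true_size_factors: list[float],
    mean_range: tuple[float, float] = (20.0, 2000.0),
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple["np.ndarray", SimulationTruth]:
    """Negative-binomial counts with per-sample size factors.

    Gene means μ_g are drawn log-uniformly from ``mean_range``; sample j's
    counts have mean s_j·μ_g and NB dispersion α (variance μ + α·μ²);
    dispersion 0 gives Poisson counts.
    """
    if any(s <= 0 for s in true_size_factors):
        raise InvalidInputError("size factors must be positive")
    if len(true_size_factors) != len(samples):
        raise InvalidInputError("one size factor per sample is required")
    if dispersion < 0:
        raise InvalidInputError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    mu = np.exp(
        rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes)
    )
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, s in enumerate(true_size_factors):
        mean = s * mu
        if dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / dispersion
            p = r / (r + mean)
            counts[:, j] = rng.negative_binomial(r, p)
    truth = SimulationTruth(
        scenario="counts",
        seed=seed,
        parameters={
            "n_genes": n_genes,
            "samples": list(samples),
            "mean_range": list(mean_range),
            "dispersion": dispersion,
        },
        records={"size_factors": list(map(float, true_size_factors))},
    )
    return counts, truth
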