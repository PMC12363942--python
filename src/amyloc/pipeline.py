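"""End-to-end pipeline orchestration from a single structured config.

The demo workflow runs entirely on synthetic data: simulate an NAHR locus,
extract it by its anchors, map gene copies, segment it into duplicons,
call the mosaic breakpoint of each simulated event, bracket a duplication
age on a supplied dated tree, and quantify a simulated paralog read
mixture.  Stage order is fixed by declared dependencies; every parameter
has a default that is echoed into the machine-readable run report.
"""

from __future__ import annotations

import json
import logging
from copy import deepcopy
from typing import Any

from . import architecture, expression, locus_extraction, synthetic
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: stages in dependency order
STAGES = ("simulate", "extract", "architecture", "date", "expression")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "out": None,  # path for the JSON run report, None = do not write
    "simulate": {
        "n_initial_genes": 2,
        "gene_len": 2000,
        "spacer_len": 800,
        "divergence": 0.02,
        "events": [[0, 1, 1000]],
        "ltr_at_junction": False,
    },
    "extract": {"min_identity": 0.85, "min_cov": 0.8},
    "architecture": {"min_support": 0.8, "max_crossover_frac": 0.2},
    "date": {
        "newick": "((((tipA:2,tipB:2):2.5,(tipC:3,tipD:3):1.5):0.5,tipE:5):5,outgrp:10);",
        "carriers": ["tipA", "tipB", "tipC", "tipD"],
    },
    "expression": {
        "mixture": [0.6, 0.3, 0.1],
        "n_reads": 2000,
        "read_len": 150,
        "error_rate": 0.002,
        # simulated paralogs are ~2% diverged, so a 150 bp read carries a
        # few legitimate non-site differences from the consensus
        "max_mismatch_elsewhere": 12,
    },
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Merge ``config`` over the defaults, rejecting unknown keys."""
    merged = deepcopy(DEFAULT_CONFIG)
    unknown = set(config) - set(merged)
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    for key, value in config.items():
        if isinstance(value, dict):
            bad = set(value) - set(merged[key])
            if bad:
                raise InvalidInputError(
                    f"unknown config keys under {key!r}: {sorted(bad)}"
                )
            merged[key].update(value)
        else:
            merged[key] = value
    bad_stages = set(merged["stages"]) - set(STAGES)
    if bad_stages:
        raise InvalidInputError(f"unknown stages: {sorted(bad_stages)}")
    # keep dependency order regardless of the order given
    merged["stages"] = [s for s in STAGES if s in merged["stages"]]
    return merged


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute the requested stages and return a machine-readable report."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    report: dict[str, Any] = {"config": cfg, "stages": {}, "warnings": []}
    state: dict[str, Any] = {}

    for stage in cfg["stages"]:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            contigs, truth = synthetic.simulate_locus_nahr(
                seed=seed,
                events=[tuple(e) for e in cfg["simulate"]["events"]],
                **{
                    k: cfg["simulate"][k]
                    for k in (
                        "n_initial_genes",
                        "gene_len",
                        "spacer_len",
                        "divergence",
                        "ltr_at_junction",
                    )
                },
            )
            state["contigs"] = contigs
            state["truth"] = truth
            report["stages"]["simulate"] = {
                "copy_number": truth.records["copy_number"],
                "block_order": truth.records["block_order"],
            }
        elif stage == "extract":
            if "truth" not in state:
                raise InvalidInputError(
                    "stage 'extract' requires the 'simulate' stage output"
                )
            truth = state["truth"]
            p = cfg["extract"]
            hits5 = locus_extraction.find_anchor_hits(
                truth.records["anchor5"], state["contigs"],
                p["min_identity"], p["min_cov"], anchor_id="anchor5",
            )
            hits3 = locus_extraction.find_anchor_hits(
                truth.records["anchor3"], state["contigs"],
                p["min_identity"], p["min_cov"], anchor_id="anchor3",
            )
            locus = locus_extraction.extract_locus(
                hits5, hits3, state["contigs"], species="synthetic"
            )
            state["locus"] = locus
            block_seqs = truth.records["block_seqs"]
            first = truth.records["block_order"][0]
            copies = locus_extraction.map_gene_copies(
                locus, {"gene": block_seqs[first]},
                p["min_identity"], p["min_cov"],
            )
            state["gene_copies"] = copies
            report["stages"]["extract"] = {
                "status": locus.status,
                "locus_length": len(locus.sequence),
                "gene_copies": len(copies),
            }
        elif stage == "architecture":
            if "locus" not in state:
                raise InvalidInputError(
                    "stage 'architecture' requires the 'extract' stage output"
                )
            segments = architecture.segment_locus(
                state["locus"], state["gene_copies"]
            )
            truth = state["truth"]
            calls = []
            block_seqs = truth.records["block_seqs"]
            for ev in truth.records["events"]:
                call = architecture.call_mosaic_breakpoints(
                    block_seqs[ev["derived"]],
                    block_seqs[ev["donor5"]],
                    block_seqs[ev["donor3"]],
                    min_support=cfg["architecture"]["min_support"],
                    labels=(ev["derived"], ev["donor5"], ev["donor3"]),
                )
                mechanism = architecture.classify_mechanism(
                    call,
                    len(block_seqs[ev["derived"]]),
                    flanks_homologous_direct=True,
                    min_support=cfg["architecture"]["min_support"],
                    max_crossover_frac=cfg["architecture"]["max_crossover_frac"],
                )
                calls.append(
                    {
                        "derived": call.derived,
                        "crossover_interval": list(call.crossover_interval),
                        "true_crossover": ev["crossover"],
                        "support5": call.support5,
                        "support3": call.support3,
                        "mechanism": mechanism,
                    }
                )
            report["stages"]["architecture"] = {
                "n_segments": len(segments),
                "segments": [
                    {"label": s.label, "interval": list(s.interval)}
                    for s in segments
                ],
                "mosaic_calls": calls,
            }
        elif stage == "date":
            tree = architecture.DatedTree.from_newick(cfg["date"]["newick"])
            bracket = architecture.bracket_duplication_age(
                tree, set(cfg["date"]["carriers"])
            )
            report["stages"]["date"] = {
                "lower_mya": bracket.lower_mya,
                "upper_mya": None
                if bracket.upper_mya == float("inf")
                else bracket.upper_mya,
                "bounding_noncarrier": bracket.bounding_noncarrier,
            }
        elif stage == "expression":
            if "truth" not in state:
                raise InvalidInputError(
                    "stage 'expression' requires the 'simulate' stage output"
                )
            truth = state["truth"]
            p = cfg["expression"]
            labels = truth.records["block_order"][: len(p["mixture"])]
            seqs = [truth.records["block_seqs"][l] for l in labels]
            aln = expression.ParalogAlignment(labels, seqs)
            sites = expression.find_diagnostic_sites(aln, max_cluster_span=p["read_len"])
            reads, _ = synthetic.simulate_reads(
                seqs, p["mixture"], p["n_reads"], p["read_len"],
                p["error_rate"], seed=seed + 1,
            )
            consensus = expression.consensus_from_alignment(aln)
            counts = expression.assign_reads(
                reads, consensus, sites,
                max_mismatch_elsewhere=p["max_mismatch_elsewhere"],
            )
            props = expression.proportional_expression(
                [counts.counts[l] for l in labels]
            )
            report["stages"]["expression"] = {
                "n_sites": len(sites.sites),
                "counts": counts.counts,
                "unassigned": counts.unassigned,
                "proportions": dict(zip(labels, map(float, props))),
                "true_mixture": p["mixture"],
            }

    if cfg["out"]:
        with open(cfg["out"], "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
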