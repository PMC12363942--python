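"""Promoter-window extraction, PWM scanning with exact p-values, and
salivary/pancreatic transcription-factor bias classification.

Promoters are fixed 170-bp windows spanning 100 bp upstream to 70 bp
downstream of the TSS, oriented in transcription direction.  Windows are
scanned on both strands with position weight matrices (JASPAR-style
counts); match p-values are exact under an i.i.d. background, computed by
dynamic-programming convolution of the per-column score distributions on a
discretized bit grid.  Transcription factors are classed as
salivary-biased, pancreatic-biased, or core from externally supplied
tissue sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import normalize, revcomp
from .errors import InvalidInputError

UPSTREAM = 100
DOWNSTREAM = 70
WINDOW_LEN = UPSTREAM + DOWNSTREAM  # 170
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 0.01
SCORE_GRANULARITY = 1e-3  # bits

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    genomic_interval: tuple[int, int]
    strand: str
    sequence: str  # transcription-oriented, upstream -> downstream


@dataclass(frozen=True)
class MotifHit:
    pwm_id: str
    gene_id: str
    offset: int  # 0-based within the window (forward window coordinates)
    strand: str
    score: float  # log-odds, bits
    p_value: float


@dataclass(frozen=True)
class TFBiasLabel:
    tf_id: str
    label: str  # salivary_biased | pancreatic_biased | core


def extract_promoter(sequence: str, tss: int, strand: str, gene_id: str = "") -> PromoterWindow:
    """Extract the 170-bp promoter window around a TSS.

    ``tss`` is the 0-based index of the +1 transcribed base.  On the plus
    strand the window is [tss−100, tss+70); on the minus strand
    [tss−69, tss+101), reverse complemented so the output always reads
    upstream → downstream with the TSS as its 101st base.  Windows
    overhanging the sequence raise (no padding).
    """
    sequence = normalize(sequence)
    if strand == "+":
        start, end = tss - UPSTREAM, tss + DOWNSTREAM
    elif strand == "-":
        start, end = tss - DOWNSTREAM + 1, tss + UPSTREAM + 1
    else:
        raise InvalidInputError(f"strand must be + or -, got {strand!r}")
    if start < 0 or end > len(sequence):
        raise InvalidInputError(
            f"promoter window [{start}, {end}) overhangs the sequence "
            f"(length {len(sequence)})"
        )
    window = sequence[start:end]
    if strand == "-":
        window = revcomp(window)
    return PromoterWindow(gene_id, (start, end), strand, window)


@dataclass
class PWM:
    """A position weight matrix: 4 × L non-negative weights (A, C, G, T rows).

    Weights may be counts or frequencies; columns are normalized
    internally.  ``background`` must sum to 1.
    """

    id: str
    matrix: np.ndarray
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise InvalidInputError("PWM must be 4 × L with L ≥ 4")
        if (self.matrix < 0).any():
            raise InvalidInputError("PWM weights must be non-negative")
        if (self.matrix.sum(axis=0) == 0).any():
            raise InvalidInputError("degenerate PWM column (all-zero)")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise InvalidInputError("background must sum to 1")
        self._freq = self.matrix / self.matrix.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background)
        self._score = np.log2(
            (self._freq + self.pseudocount)
            / (bg[:, None] * (1.0 + 4.0 * self.pseudocount))
        )
        # integer grid scores for the exact p-value DP
        self._grid = np.rint(self._score / SCORE_GRANULARITY).astype(int)
        self._distribution_cache: tuple[np.ndarray, int] | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def column_scores(self) -> np.ndarray:
        return self._score

    def grid_scores(self) -> np.ndarray:
        return self._grid

    def score_word(self, word: str) -> float:
        """Real-valued log-odds score; N scores as the worst allele."""
        total = 0.0
        for i, b in enumerate(word):
            if b in _BASE_INDEX:
                total += self._score[_BASE_INDEX[b], i]
            else:
                total += float(self._score[:, i].min())
        return total

    def _grid_score_word(self, word: str) -> int:
        total = 0
        for i, b in enumerate(word):
            if b in _BASE_INDEX:
                total += self._grid[_BASE_INDEX[b], i]
            else:  # N scores as the worst allele of the column
                total += int(self._grid[:, i].min())
        return total

    def _survival(self) -> tuple[np.ndarray, int]:
        """P(grid score ≥ s) under the i.i.d. background, exact.

        Returns (survival array, offset) such that survival[s - offset]
        is the tail probability for integer grid score s.
        """
        if self._distribution_cache is not None:
            return self._distribution_cache
        bg = np.asarray(self.background)
        mins = self._grid.min(axis=0)
        maxs = self._grid.max(axis=0)
        offset = int(mins.sum())
        size = int(maxs.sum()) - offset + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        pos = 0
        for i in range(self.length):
            new = np.zeros(size)
            for b in range(4):
                shift = int(self._grid[b, i] - mins[i])
                new[shift : shift + pos + 1] += bg[b] * dist[: pos + 1]
            pos += int(maxs[i] - mins[i])
            dist = new
        survival = np.cumsum(dist[::-1])[::-1]
        self._distribution_cache = (survival, offset)
        return survival, offset

    def p_value(self, word_or_grid_score) -> float:
        """Exact P(score ≥ s) for a word or an integer grid score."""
        if isinstance(word_or_grid_score, str):
            s = self._grid_score_word(word_or_grid_score)
        else:
            s = int(word_or_grid_score)
        survival, offset = self._survival()
        idx = s - offset
        if idx <= 0:
            return 1.0
        if idx >= len(survival):
            return 0.0
        return float(survival[idx])


def read_jaspar(path_or_text: str) -> list[PWM]:
    """Parse JASPAR-style PFM text (``>id`` then four ``A [ ... ]`` rows).

    Accepts either a path or the raw text.
    """
    import os

    text = (
        open(path_or_text).read()
        if os.path.exists(path_or_text)
        else path_or_text
    )
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: dict[str, list[float]] = {}
    order = "ACGT"

    def flush():
        nonlocal current_id, rows
        if current_id is not None:
            if set(rows) != set(order):
                raise InvalidInputError(
                    f"motif {current_id}: expected A/C/G/T rows, got {sorted(rows)}"
                )
            matrix = np.array([rows[b] for b in order])
            pwms.append(PWM(current_id, matrix))
        current_id, rows = None, {}

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0]
        else:
            base = line[0].upper()
            numbers = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(v) for v in numbers]
    flush()
    return pwms


def pwm_scan(
    pwm: PWM,
    window: PromoterWindow,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[MotifHit]:
    """Scan both strands of a promoter window with a PWM.

    All offsets are reported in forward window coordinates; minus-strand
    hits are positions where the reverse complement of the motif matches.
    Hits with exact p-value < ``p_threshold`` are returned sorted by
    ascending p (all overlaps kept).  N bases score as the worst allele of
    their column.
    """
    seq = window.sequence
    L = pwm.length
    hits: list[MotifHit] = []
    n = len(seq)
    for strand in "+-":
        scan_seq = seq if strand == "+" else revcomp(seq)
        for off in range(n - L + 1):
            word = scan_seq[off : off + L]
            grid = pwm._grid_score_word(word)
            p = pwm.p_value(grid)
            if p < p_threshold:
                fwd_off = off if strand == "+" else n - off - L
                hits.append(
                    MotifHit(
                        pwm_id=pwm.id,
                        gene_id=window.gene_id,
                        offset=fwd_off,
                        strand=strand,
                        score=pwm.score_word(word),
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.p_value, h.offset, h.strand))
    return hits


def classify_tf_bias(
    salivary_sets: list[set[str]],
    pancreatic_set: set[str],
    universe: set[str],
) -> list[TFBiasLabel]:
    """Classify each TF in ``universe``.

    Salivary-biased: present in at least one salivary set and absent from
    the pancreatic set.  Pancreatic-biased: the converse.  Everything else
    (including TFs in both) is core.
    """
    salivary_union = set().union(*salivary_sets) if salivary_sets else set()
    for s in [salivary_union, pancreatic_set]:
        if not s <= universe:
            raise InvalidInputError("tissue sets must be subsets of the universe")
    labels = []
    for tf in sorted(universe):
        in_sal = tf in salivary_union
        in_pan = tf in pancreatic_set
        if in_sal and not in_pan:
            label = "salivary_biased"
        elif in_pan and not in_sal:
            label = "pancreatic_biased"
        else:
            label = "core"
        labels.append(TFBiasLabel(tf, label))
    return labels
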