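"""Small nucleotide-sequence utilities used throughout the package.

Coordinates are 0-based half-open everywhere; minus-strand intervals always
refer to the forward strand of the source sequence.
"""

from __future__ import annotations

from .errors import InvalidInputError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_ALPHABET = frozenset("ACGTN")


def normalize(seq: str, *, allow_empty: bool = False) -> str:
    """Uppercase ``seq`` and verify it is drawn from {A,C,G,T,N}."""
    s = seq.upper()
    if not s and not allow_empty:
        raise InvalidInputError("empty nucleotide sequence")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise InvalidInputError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def wrap_fasta(header: str, seq: str, width: int = 80) -> str:
    lines = [f">{header}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)] or [""]
    return "\n".join(lines) + "\n"
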