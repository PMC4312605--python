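"""Small nucleotide-string helpers shared across the pipeline.

All sequences are stored internally in the DNA alphabet (U folded onto T,
uppercase); references and reads in mixed RNA/DNA conventions are normalised
on input.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NUCLEOTIDES = frozenset("ACGT")
VALID_INPUT = frozenset("ACGTUN")


def normalize(seq: str) -> str:
    """Uppercase and fold U onto T."""
    return seq.upper().replace("U", "T")


def check_nucleotides(seq: str, allow_n: bool = True) -> str:
    """Normalise *seq* and raise ``ValueError`` on non-nucleotide characters."""
    s = normalize(seq)
    allowed = VALID_INPUT if allow_n else NUCLEOTIDES
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]
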