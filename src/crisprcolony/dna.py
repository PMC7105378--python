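"""Shared DNA-string primitives.

All sequences are plain upper-case Python strings over ``ACGT`` (``N``
allowed in reads).  Helpers here are deliberately small; anything format
related lives in :mod:`crisprcolony.io`.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (case preserved, ``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def matches_iupac(seq: str, pattern: str) -> bool:
    """True if *seq* matches the IUPAC *pattern* base-for-base.

    Lengths must be equal; an ``N`` in *seq* only matches an ``N`` in the
    pattern (ambiguity in reads does not satisfy concrete pattern bases).
    """
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq.upper(), pattern.upper()))


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes (zero-copy view)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random sequence with the given expected GC fraction."""
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def substitute(base: str, rng: np.random.Generator) -> str:
    """A base drawn uniformly from the three alternatives to *base*."""
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(len(choices))]
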