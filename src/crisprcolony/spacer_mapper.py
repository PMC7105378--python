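"""Spacer-to-protospacer mapping with PAM validation and escape typing.

Coordinates are 0-based, half-open throughout: a hit occupies the genome
interval ``[start, start + len(spacer))`` regardless of strand.  The PAM is
read immediately 3' of the protospacer *on the protospacer-bearing strand*,
so for a minus-strand hit it is the reverse complement of the genome bases
just upstream of ``start``.

Mapping is substitution-only (Hamming); no gapped alignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .dna import matches_iupac, revcomp, seq_to_array

__all__ = [
    "ProtospacerHit",
    "EscapeCall",
    "map_spacer",
    "map_spacers",
    "validate_pam",
    "extract_target",
    "classify_escape_mutation",
    "brute_force_map_spacer",
]

DEFAULT_PAM = "NGG"
DEFAULT_SEED_LEN = 8
DEFAULT_MAX_MISMATCHES = 2


@dataclass
class ProtospacerHit:
    """Location of a spacer's target on the phage genome.

    ``pam`` is the motif-length sequence immediately 3' of the protospacer
    on the protospacer strand (empty when the window runs off the genome,
    in which case ``off_end`` is set).  ``ambiguous`` flags spacers with two
    or more equally good locations; such hits are excluded from distance
    analyses downstream.
    """

    spacer: str
    start: int
    strand: str  # "+" | "-"
    pam: str
    mismatches: int
    ambiguous: bool = False
    off_end: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.spacer)


@dataclass(frozen=True)
class EscapeCall:
    """Classification of target mutations in an escaper phage.

    ``positions`` use PAM-proximal numbering: protospacer bases are 1..L
    counted from the PAM-proximal (3') end, and PAM bases are <= 0
    (0 = PAM base adjacent to the protospacer, -1 the next one out).
    ``category`` is ``none`` iff ``positions`` is empty; with multiple
    mutations the precedence is PAM > seed > distal.
    """

    category: str  # "seed" | "PAM" | "distal" | "none"
    positions: tuple[int, ...] = field(default_factory=tuple)


def _mismatch_profile(genome_arr: np.ndarray, probe: str) -> np.ndarray:
    """Hamming distance of *probe* against every window of the genome."""
    p = seq_to_array(probe)
    n = len(genome_arr) - len(p) + 1
    mm = np.zeros(max(n, 0), dtype=np.int32)
    for j in range(len(p)):
        mm += genome_arr[j : j + n] != p[j]
    return mm


def _pam_at(genome: str, start: int, length: int, strand: str, pam_len: int) -> tuple[str, bool]:
    """PAM sequence for a hit, plus an off-genome-end flag."""
    if strand == "+":
        lo, hi = start + length, start + length + pam_len
        if hi > len(genome):
            return "", True
        return genome[lo:hi], False
    lo, hi = start - pam_len, start
    if lo < 0:
        return "", True
    return revcomp(genome[lo:hi]), False


def map_spacer(
    spacer: str,
    genome: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    pam: str = DEFAULT_PAM,
    require_pam: bool = True,
) -> ProtospacerHit | None:
    """Best protospacer location for *spacer* over both genome strands.

    The best hit minimises mismatches; with ``require_pam`` only locations
    whose downstream motif matches *pam* (IUPAC semantics) are eligible.
    Returns ``None`` when no eligible location is within *max_mismatches*
    (the spacer is unmapped — recorded by callers, never fatal).  When two
    or more locations tie at the best score the returned hit (smallest
    start, ``+`` before ``-``) carries ``ambiguous=True``.
    """
    if len(spacer) < 15:
        raise ValueError("spacer too short to map (need >= 15 nt)")
    if len(genome) < len(spacer):
        return None
    garr = seq_to_array(genome)
    pam_len = len(pam)
    candidates: list[tuple[int, int, str, str, bool]] = []  # (mm, start, strand, pam, off_end)
    for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
        mm = _mismatch_profile(garr, probe)
        for start in np.nonzero(mm <= max_mismatches)[0]:
            pam_seq, off_end = _pam_at(genome, int(start), len(spacer), strand, pam_len)
            if require_pam and (off_end or not matches_iupac(pam_seq, pam)):
                continue
            candidates.append((int(mm[start]), int(start), strand, pam_seq, off_end))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best_mm = candidates[0][0]
    n_best = sum(1 for c in candidates if c[0] == best_mm)
    mmv, start, strand, pam_seq, off_end = candidates[0]
    return ProtospacerHit(
        spacer=spacer,
        start=start,
        strand=strand,
        pam=pam_seq,
        mismatches=mmv,
        ambiguous=n_best >= 2,
        off_end=off_end,
    )


def map_spacers(
    spacers: Iterable[str],
    genome: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    pam: str = DEFAULT_PAM,
    require_pam: bool = True,
) -> dict[str, ProtospacerHit | None]:
    """Map many (deduplicated) spacers; unmapped spacers map to ``None``."""
    hits: dict[str, ProtospacerHit | None] = {}
    for s in spacers:
        if s not in hits:
            hits[s] = map_spacer(s, genome, max_mismatches, pam, require_pam)
    return hits


def validate_pam(genome: str, hit: ProtospacerHit, pam_pattern: str = DEFAULT_PAM) -> bool:
    """True iff the bases 3' of the protospacer match *pam_pattern*.

    A PAM window running off the genome end returns ``False`` and sets
    ``hit.off_end``.
    """
    pam_seq, off_end = _pam_at(genome, hit.start, len(hit.spacer), hit.strand, len(pam_pattern))
    if off_end:
        hit.off_end = True
        return False
    return matches_iupac(pam_seq, pam_pattern)


def extract_target(genome: str, hit: ProtospacerHit, pam_len: int = 3) -> str:
    """Protospacer + PAM, oriented PAM-distal -> PAM-proximal (PAM last)."""
    if hit.strand == "+":
        return genome[hit.start : hit.end + pam_len]
    return revcomp(genome[hit.start - pam_len : hit.end])


def classify_escape_mutation(
    wild_target: str,
    mutant_target: str,
    seed_len: int = DEFAULT_SEED_LEN,
    pam_len: int = 3,
) -> EscapeCall:
    """Type the mutations distinguishing an escaper target from the wild type.

    Both inputs span protospacer + PAM with the protospacer written
    PAM-distal -> PAM-proximal (as returned by :func:`extract_target`).
    Positions are numbered PAM-proximally (see :class:`EscapeCall`); the
    category follows the precedence PAM > seed > distal, with the seed being
    the *seed_len* PAM-proximal protospacer bases.
    """
    if len(wild_target) != len(mutant_target):
        raise ValueError("wild and mutant targets must have equal length")
    if len(wild_target) <= pam_len:
        raise ValueError("target must be longer than the PAM")
    proto_len = len(wild_target) - pam_len
    positions = tuple(
        proto_len - i
        for i, (w, m) in enumerate(zip(wild_target, mutant_target))
        if w != m
    )
    if not positions:
        return EscapeCall(category="none")
    if any(p <= 0 for p in positions):
        category = "PAM"
    elif any(1 <= p <= seed_len for p in positions):
        category = "seed"
    else:
        category = "distal"
    return EscapeCall(category=category, positions=positions)


def brute_force_map_spacer(
    spacer: str,
    genome: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    pam: str = DEFAULT_PAM,
    require_pam: bool = True,
) -> ProtospacerHit | None:
    """Independent exhaustive reference for :func:`map_spacer`.

    Character-by-character Hamming scan of every window on both strands,
    applying the same eligibility and tie rules.  Used by the
    oracle-equivalence checks.
    """
    pam_len = len(pam)
    candidates = []
    for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
        for start in range(len(genome) - len(spacer) + 1):
            window = genome[start : start + len(spacer)]
            d = sum(a != b for a, b in zip(window, probe))
            if d > max_mismatches:
                continue
            pam_seq, off_end = _pam_at(genome, start, len(spacer), strand, pam_len)
            if require_pam and (off_end or not matches_iupac(pam_seq, pam)):
                continue
            candidates.append((d, start, strand, pam_seq, off_end))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    d, start, strand, pam_seq, off_end = candidates[0]
    n_best = sum(1 for c in candidates if c[0] == d)
    return ProtospacerHit(
        spacer=spacer,
        start=start,
        strand=strand,
        pam=pam_seq,
        mismatches=d,
        ambiguous=n_best >= 2,
        off_end=off_end,
    )
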