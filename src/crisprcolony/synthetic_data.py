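"""Synthetic inputs for every stage of the pipeline.

Generates phage genomes, clonal colonies whose cells share a founder spacer
plus priming-biased additional spacers, amplicon reads of the expanded
locus, phage populations containing escaper mutants, Poisson spot-assay
counts, and ordinal time-shift resistance matrices — all seeded and
reproducible, so downstream modules are testable without external data.

Acquisition model
-----------------
Each simulated cell starts with the founder spacer.  Additional spacers are
appended by geometric stopping: while a uniform draw falls below
``priming_prob`` another spacer is acquired, capped at 4 spacers total (the
largest array size handled by the pipeline).  Hence the expected fraction of
multi-spacer cells equals ``priming_prob`` exactly.  Each additional
spacer's target is drawn from a mixture: with probability ``local_fraction``
uniformly among valid protospacers within ``local_window`` bp of the founder
target, otherwise uniformly among all valid protospacers.  The genome is
linear; windows are truncated at the ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import spacer_mapper
from .array_parser import SpacerArray
from .dna import random_seq, revcomp, substitute
from .escape_assay import PlaqueAssay
from .timeshift import ResistanceMatrix

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "InvalidTargetError",
    "SimulatedColony",
    "SpacerTruth",
    "PhageVariant",
    "PhagePopulation",
    "generate_phage_genome",
    "valid_protospacer_starts",
    "simulate_colony",
    "simulate_reads",
    "simulate_escaper_population",
    "simulate_plaque_assay",
    "simulate_timeshift",
]

MAX_ARRAY_SIZE = 4

# 36-bp type II-A direct repeat (S. pyogenes SF370 CRISPR locus).
DEFAULT_REPEAT = "GTTTTAGAGCTATGCTGTTTTGAATGGTCCCAAAAC"
DEFAULT_LEADER = "ATAAGGAAGTAACTTATCAAAGAGGTTTTAGGATCA"


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class InvalidTargetError(ValueError):
    """A requested protospacer position has no valid PAM / is absent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Rates mirror the empirical regime of the modelled system: naive
    acquisition around 1e-7 per infected cell, escaper frequencies of
    1e-6..1e-8 per phage, and priming biased to a +/-500 bp window around
    the founder target.
    """

    genome_length: int = 30_000
    gc_content: float = 0.35
    repeat_seq: str = DEFAULT_REPEAT
    leader_seq: str = DEFAULT_LEADER
    barcode_length: int = 10
    spacer_length: int = 30
    naive_rate: float = 1e-7
    priming_prob: float = 0.05
    local_fraction: float = 0.8
    local_window: int = 500
    escape_freq: float = 1e-6
    read_error_rate: float = 0.001
    pam: str = "NGG"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "naive_rate", "priming_prob", "local_fraction",
                     "escape_freq", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.genome_length <= 2 * self.spacer_length:
            raise ConfigurationError("genome_length must exceed 2 x spacer_length")
        if not self.repeat_seq:
            raise ConfigurationError("repeat_seq must be nonempty")
        if self.repeat_seq == self.leader_seq:
            raise ConfigurationError("repeat_seq must differ from leader_seq")
        if self.local_window <= 0:
            raise ConfigurationError("local_window must be positive")
        if self.barcode_length <= 0 or self.spacer_length <= 0:
            raise ConfigurationError("barcode_length and spacer_length must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class SpacerTruth:
    """Ground-truth provenance of one simulated spacer."""

    position: int
    strand: str
    primed: bool


@dataclass
class SimulatedColony:
    """A clonal colony: arrays share one founder spacer and one barcode.

    ``arrays`` hold spacers leader-proximal first, so the founder spacer is
    the *last* element of every array (new spacers insert at the leader
    end).  ``truth_labels[i][j]`` describes ``arrays[i].spacers[j]``.
    """

    founder_spacer: str
    founder_position: int
    founder_strand: str
    barcode: str
    arrays: list[SpacerArray] = field(default_factory=list)
    truth_labels: list[tuple[SpacerTruth, ...]] = field(default_factory=list)


@dataclass(frozen=True)
class PhageVariant:
    genome: str
    count: int
    label: str


@dataclass(frozen=True)
class PhagePopulation:
    """A phage stock as a small set of genome variants with counts."""

    variants: tuple[PhageVariant, ...]

    @property
    def total(self) -> int:
        return sum(v.count for v in self.variants)


def generate_phage_genome(config: GeneratorConfig, rng: np.random.Generator | None = None) -> str:
    """Random linear genome of ``config.genome_length`` at ``gc_content``."""
    if config.genome_length < 1000:
        raise ConfigurationError("genome_length must be >= 1000")
    rng = config.rng() if rng is None else rng
    return random_seq(config.genome_length, rng, gc=config.gc_content)


def valid_protospacer_starts(
    genome: str, spacer_length: int, pam: str = "NGG"
) -> list[tuple[int, str]]:
    """All ``(start, strand)`` with a valid PAM immediately 3' of the target.

    Plus strand: PAM occupies ``[start+L, start+L+len(pam))``.  Minus
    strand: the PAM is the reverse complement of ``[start-len(pam), start)``.
    Vectorized (the generator calls this once per simulated colony).
    """
    from .dna import IUPAC, seq_to_array

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    g = seq_to_array(genome)
    n = len(genome) - spacer_length + 1
    if n <= 0:
        return []
    positions = np.arange(n)
    plus_ok = np.ones(n, dtype=bool)
    minus_ok = np.ones(n, dtype=bool)
    for k, p in enumerate(pam.upper()):
        allowed = np.frombuffer(IUPAC[p].encode(), dtype=np.uint8)
        idx = positions + spacer_length + k
        in_range = idx < len(genome)
        ok = np.zeros(n, dtype=bool)
        ok[in_range] = np.isin(g[idx[in_range]], allowed)
        plus_ok &= ok
        # minus strand: pam[k] must be the complement of genome[start-1-k]
        allowed_c = np.frombuffer(
            "".join(comp[b] for b in IUPAC[p]).encode(), dtype=np.uint8
        )
        idx_m = positions - 1 - k
        in_range_m = idx_m >= 0
        ok_m = np.zeros(n, dtype=bool)
        ok_m[in_range_m] = np.isin(g[idx_m[in_range_m]], allowed_c)
        minus_ok &= ok_m
    out = [(int(s), "+") for s in np.nonzero(plus_ok)[0]]
    out += [(int(s), "-") for s in np.nonzero(minus_ok)[0]]
    out.sort()
    return out


def _spacer_at(genome: str, start: int, strand: str, length: int) -> str:
    seq = genome[start : start + length]
    return seq if strand == "+" else revcomp(seq)


def simulate_colony(
    genome: str,
    founder_position: int,
    n_cells: int,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    founder_strand: str = "+",
) -> SimulatedColony:
    """Simulate *n_cells* cells descending from one spacer-acquiring founder.

    Every cell's array carries the founder spacer (leader-distal); extra
    spacers follow the acquisition model documented in the module docstring,
    with truth labels recorded per spacer.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = config.rng() if rng is None else rng
    L = config.spacer_length
    candidates = valid_protospacer_starts(genome, L, config.pam)
    if (founder_position, founder_strand) not in set(candidates):
        raise InvalidTargetError(
            f"founder_position {founder_position}{founder_strand} has no valid "
            f"{config.pam} PAM"
        )
    local = [
        (s, st) for s, st in candidates if abs(s - founder_position) <= config.local_window
    ]
    founder_spacer = _spacer_at(genome, founder_position, founder_strand, L)
    founder_truth = SpacerTruth(founder_position, founder_strand, primed=False)
    barcode = random_seq(config.barcode_length, rng)
    colony = SimulatedColony(
        founder_spacer=founder_spacer,
        founder_position=founder_position,
        founder_strand=founder_strand,
        barcode=barcode,
    )
    for i in range(n_cells):
        acquired: list[tuple[str, SpacerTruth]] = [(founder_spacer, founder_truth)]
        while len(acquired) < MAX_ARRAY_SIZE and rng.random() < config.priming_prob:
            pool = local if (local and rng.random() < config.local_fraction) else candidates
            s, st = pool[rng.integers(len(pool))]
            acquired.append(
                (_spacer_at(genome, s, st, L), SpacerTruth(s, st, primed=True))
            )
        ordered = list(reversed(acquired))  # leader-proximal (newest) first
        colony.arrays.append(
            SpacerArray(
                spacers=tuple(seq for seq, _ in ordered),
                barcode=barcode,
                read_id=f"cell{i}",
            )
        )
        colony.truth_labels.append(tuple(truth for _, truth in ordered))
    return colony


def amplicon_sequence(array: SpacerArray, config: GeneratorConfig) -> str:
    """Error-free amplicon: barcode + leader + repeat + (spacer + repeat)*n."""
    parts = [array.barcode or "", config.leader_seq, config.repeat_seq]
    for spacer in array.spacers:
        parts.append(spacer)
        parts.append(config.repeat_seq)
    return "".join(parts)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(mask)[0]:
        chars[i] = substitute(chars[i], rng)
    return "".join(chars)


def simulate_reads(
    colony: SimulatedColony,
    config: GeneratorConfig,
    reads_per_array: int = 1,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Amplicon reads for every array, with per-base substitution errors.

    Returns ``(read_id, sequence)`` pairs; read ids are
    ``{array.read_id}_r{k}``.  Write as FASTQ with :func:`crisprcolony.io.write_fastq`.
    """
    if reads_per_array < 1:
        raise ConfigurationError("reads_per_array must be >= 1")
    rng = config.rng() if rng is None else rng
    reads: list[tuple[str, str]] = []
    for array in colony.arrays:
        template = amplicon_sequence(array, config)
        for k in range(reads_per_array):
            reads.append(
                (f"{array.read_id}_r{k}", _apply_errors(template, config.read_error_rate, rng))
            )
    return reads


def simulate_escaper_population(
    genome: str,
    protospacer: str,
    escape_freq: float,
    mutation_class: str,
    n_phage: int,
    seed: int,
    pam: str = "NGG",
    seed_len: int = spacer_mapper.DEFAULT_SEED_LEN,
) -> PhagePopulation:
    """Phage stock of *n_phage* genomes containing escaper mutants.

    The escaper count is Poisson with mean ``escape_freq * n_phage``; every
    escaper carries one substitution drawn uniformly in the designated
    region — the *seed_len* PAM-proximal protospacer bases for
    ``mutation_class='seed'``, or the non-degenerate PAM bases for
    ``mutation_class='PAM'`` (mutating an ``N`` would not abolish targeting).
    """
    if mutation_class not in ("seed", "PAM"):
        raise ValueError("mutation_class must be 'seed' or 'PAM'")
    if not 0.0 <= escape_freq <= 1.0:
        raise ValueError("escape_freq must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hit = spacer_mapper.map_spacer(protospacer, genome, max_mismatches=0, pam=pam,
                                   require_pam=True)
    if hit is None:
        raise InvalidTargetError("protospacer not found on the genome with a valid PAM")
    # Genome indices of the mutable region, strand-aware.
    if mutation_class == "seed":
        if hit.strand == "+":
            region = list(range(hit.end - seed_len, hit.end))
        else:
            region = list(range(hit.start, hit.start + seed_len))
    else:
        pam_offsets = [i for i, p in enumerate(pam.upper()) if p != "N"]
        if hit.strand == "+":
            region = [hit.end + i for i in pam_offsets]
        else:
            region = [hit.start - 1 - i for i in pam_offsets]
    n_escapers = int(rng.poisson(escape_freq * n_phage))
    n_escapers = min(n_escapers, n_phage)
    variants = [PhageVariant(genome=genome, count=n_phage - n_escapers, label="wild-type")]
    if n_escapers > 0:
        pos = region[rng.integers(len(region))]
        mutated = genome[:pos] + substitute(genome[pos], rng) + genome[pos + 1 :]
        variants.append(PhageVariant(genome=mutated, count=n_escapers, label="escaper"))
    return PhagePopulation(variants=tuple(variants))


def _escapes_all(variant_genome: str, host_spacers: Sequence[str], pam: str) -> bool:
    """True iff no host spacer retains a perfect, PAM-valid target."""
    for spacer in host_spacers:
        if spacer_mapper.map_spacer(spacer, variant_genome, max_mismatches=0,
                                    pam=pam, require_pam=True) is not None:
            return False
    return True


def simulate_plaque_assay(
    population: PhagePopulation,
    host_spacers: Sequence[str],
    dilution_factors: Sequence[float],
    seed: int,
    host_id: str = "host",
    volume_ml: float = 1.0,
    pam: str = "NGG",
) -> PlaqueAssay:
    """Poisson spot counts for a dilution series on one host lawn.

    A phage variant forms plaques iff it escapes *every* host spacer
    (targeting requires a perfect protospacer match with a valid PAM).
    Counts at dilution ``d`` are Poisson with mean
    ``escaping_total * d * volume_ml``; with ``volume_ml = 1`` the estimated
    titer equals the escaping PFU of the stock.
    """
    if any(d <= 0 for d in dilution_factors):
        raise ValueError("dilution factors must be positive")
    rng = np.random.default_rng(seed)
    escaping = sum(v.count for v in population.variants
                   if _escapes_all(v.genome, host_spacers, pam))
    spots = [(float(d), int(rng.poisson(escaping * d * volume_ml)))
             for d in dilution_factors]
    return PlaqueAssay(
        host_id=host_id,
        spot_counts=spots,
        plated_volume=volume_ml,
        stock_titer=population.total / volume_ml,
    )


def simulate_timeshift(
    n_colonies: int,
    timepoints: Sequence[int],
    improvement_rule: str,
    seed: int,
    host_gain: float = 2.0,
    phage_gain: float = 1.0,
    noise: float = 0.0,
    founder_id: str = "founder",
) -> ResistanceMatrix:
    """Ordinal host x phage resistance matrix under a documented toy rule.

    Hosts: the founder at time 0 plus *n_colonies* per post-infection time
    point.  Phages: *n_colonies* stock isolates at time 0 plus *n_colonies*
    per time point.  Under ``improvement_rule='monotone'`` each host gets a
    resistance level ``host_gain * (time index)`` and each phage an
    infectivity level ``phage_gain * (time index)`` (plus optional Gaussian
    noise); the score is 1 where resistance exceeds infectivity by more than
    0.25, 0 where it trails by more than 0.25, 0.5 otherwise.  With
    ``host_gain >= phage_gain`` the expected contemporary resistance of
    later hosts is non-decreasing.  ``improvement_rule='none'`` holds all
    levels at zero, so every score is identical (0.5).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    tps = list(timepoints)
    if tps != sorted(tps):
        raise ValueError("timepoints must be ordered")
    if improvement_rule not in ("none", "monotone"):
        raise ValueError("improvement_rule must be 'none' or 'monotone'")
    rng = np.random.default_rng(seed)
    all_tps = [0] + tps
    hosts: list[tuple[str, int]] = [(founder_id, 0)]
    hosts += [(f"h{tp}_{i}", tp) for tp in tps for i in range(n_colonies)]
    phages: list[tuple[str, int]] = [(f"stock_{i}", 0) for i in range(n_colonies)]
    phages += [(f"p{tp}_{i}", tp) for tp in tps for i in range(n_colonies)]

    def level(tp: int, gain: float) -> float:
        if improvement_rule == "none":
            return 0.0
        base = gain * all_tps.index(tp)
        return base + (rng.normal(0.0, noise) if noise > 0 else 0.0)

    h_levels = [level(tp, host_gain) for _, tp in hosts]
    p_levels = [level(tp, phage_gain) for _, tp in phages]
    scores = np.empty((len(hosts), len(phages)))
    for i, hl in enumerate(h_levels):
        for j, pl in enumerate(p_levels):
            diff = hl - pl
            scores[i, j] = 1.0 if diff > 0.25 else (0.0 if diff < -0.25 else 0.5)
    return ResistanceMatrix(hosts=hosts, phages=phages, scores=scores)
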