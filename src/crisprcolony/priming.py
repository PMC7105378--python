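"""First-to-second spacer distance distribution and local enrichment.

"First" and "second" spacers are chronological, i.e. counted from the
leader-DISTAL end of the array: new spacers insert at the leader, so the
founder (first-acquired) spacer is the last array element and the second
acquired spacer is the second-to-last.  This reading is the single most
consequential convention in the module and is applied throughout.

Signed distances are ``second.start - first.start`` on the linear genome
(no wraparound).  Histograms count DISTINCT second-spacer sequences per
bin, so read duplication does not inflate counts; the enrichment report
gives both per-pair and per-distinct-sequence fractions (per-pair is the
statistically faithful quantity for recovering the generator's mixture
weight, since heavily primed draws collide on the few local protospacers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .array_parser import SpacerArray
from .spacer_mapper import ProtospacerHit

__all__ = [
    "SpacerPair",
    "PairExtraction",
    "DistanceHistogram",
    "EnrichmentReport",
    "EmptyReportError",
    "extract_pairs",
    "distance_histogram",
    "local_enrichment",
]

DEFAULT_BIN_WIDTH = 1000
DEFAULT_WINDOW = 500


class EmptyReportError(ValueError):
    """Enrichment requested for zero usable pairs."""


@dataclass(frozen=True)
class SpacerPair:
    """Chronological (first, second) spacer targets from one read."""

    colony_id: str
    first_hit: ProtospacerHit
    second_hit: ProtospacerHit

    @property
    def signed_distance(self) -> int:
        return self.second_hit.start - self.first_hit.start


@dataclass
class PairExtraction:
    """Pairs retained plus the drop accounting (candidates = used + dropped)."""

    pairs: list[SpacerPair] = field(default_factory=list)
    n_candidates: int = 0
    n_dropped: int = 0

    @property
    def n_used(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DistanceHistogram:
    """Distinct-second-spacer counts per signed distance bin.

    Bin keys are bin start coordinates (multiples of ``bin_width``); the
    origin (distance 0) lies in the bin ``[0, bin_width)``.
    """

    bin_width: int
    bins: dict[int, int]

    @property
    def total_distinct(self) -> int:
        return sum(self.bins.values())


@dataclass(frozen=True)
class EnrichmentReport:
    """Observed vs. uniform-null local fraction of second-spacer targets."""

    window: int
    n_pairs: int
    n_local_pairs: int
    observed_fraction: float  # per pair
    n_distinct: int
    n_local_distinct: int
    observed_fraction_distinct: float
    expected_fraction: float  # uniform null, end-corrected
    ratio: float  # observed_fraction / expected_fraction
    ratio_distinct: float
    p_value: float  # one-sided binomial tail, per-pair counts


def extract_pairs(
    arrays: Sequence[SpacerArray],
    hits: Mapping[str, ProtospacerHit | None],
    colony_id: str = "",
) -> PairExtraction:
    """One chronological (first, second) pair per read with >= 2 spacers.

    The first spacer is the leader-distal array element, the second the one
    before it.  Pairs whose members are unmapped or ambiguous are dropped
    and counted in ``n_dropped``.
    """
    result = PairExtraction()
    for array in arrays:
        if array.n_spacers < 2:
            continue
        result.n_candidates += 1
        first_seq = array.spacers[-1]
        second_seq = array.spacers[-2]
        first = hits.get(first_seq)
        second = hits.get(second_seq)
        if first is None or second is None or first.ambiguous or second.ambiguous:
            result.n_dropped += 1
            continue
        result.pairs.append(
            SpacerPair(
                colony_id=colony_id or array.read_id,
                first_hit=first,
                second_hit=second,
            )
        )
    return result


def distance_histogram(
    pairs: Sequence[SpacerPair], bin_width: int = DEFAULT_BIN_WIDTH
) -> DistanceHistogram:
    """Bin signed distances, counting each second-spacer sequence once per bin.

    Each pair's own first-spacer target is the origin; a sequence recurring
    in many reads contributes one count to each bin it lands in.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    seen: dict[int, set[str]] = {}
    for pair in pairs:
        b = (pair.signed_distance // bin_width) * bin_width
        seen.setdefault(b, set()).add(pair.second_hit.spacer)
    return DistanceHistogram(
        bin_width=bin_width,
        bins={b: len(s) for b, s in sorted(seen.items())},
    )


def local_enrichment(
    pairs: Sequence[SpacerPair],
    window: int = DEFAULT_WINDOW,
    genome_length: int | None = None,
) -> EnrichmentReport:
    """Enrichment of second-spacer targets within *window* bp of the first.

    The expected fraction under uniform placement is ``2*window /
    genome_length`` corrected for genome ends (the admissible interval is
    clipped to ``[0, genome_length]`` around each pair's first target and
    averaged over pairs).  The p-value is the one-sided binomial tail
    probability of the per-pair local count against that null.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not pairs:
        raise EmptyReportError("no pairs to analyze")
    if genome_length is None:
        raise ValueError("genome_length is required for the uniform null")

    n = len(pairs)
    local_pairs = [p for p in pairs if abs(p.signed_distance) <= window]
    k = len(local_pairs)

    distinct = {p.second_hit.spacer for p in pairs}
    local_distinct = {p.second_hit.spacer for p in local_pairs}

    expected = 0.0
    for p in pairs:
        f = p.first_hit.start
        span = min(genome_length, f + window) - max(0, f - window)
        expected += span / genome_length
    expected /= n

    observed = k / n
    observed_distinct = len(local_distinct) / len(distinct)
    p_value = float(stats.binom.sf(k - 1, n, expected)) if expected > 0 else float(k > 0)
    return EnrichmentReport(
        window=window,
        n_pairs=n,
        n_local_pairs=k,
        observed_fraction=observed,
        n_distinct=len(distinct),
        n_local_distinct=len(local_distinct),
        observed_fraction_distinct=observed_distinct,
        expected_fraction=expected,
        ratio=observed / expected if expected > 0 else float("inf"),
        ratio_distinct=observed_distinct / expected if expected > 0 else float("inf"),
        p_value=p_value,
    )
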