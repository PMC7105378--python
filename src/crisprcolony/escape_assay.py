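"""Phage-escape quantification: titers, EOP, detection limits, spike-ins.

Titers come from spot/dilution series; ``dilution_factor`` is the fraction
of the stock present in the plated spot (a 10^-6 dilution has factor 1e-6),
so ``titer = plaques / (dilution_factor * volume)``.  EOP (efficiency of
plaquing) is the plaque count on a test strain relative to the total phage
particles in the stock; for a host carrying a single targeting spacer it
equals the escaper frequency of that spacer in the stock.
"""

from __future__ import annotations

from dataclasses import dataclass
from scipy import stats

__all__ = [
    "PlaqueAssay",
    "TiterResult",
    "EopResult",
    "UndefinedEopError",
    "titer",
    "eop",
    "spike_escapers",
    "moi",
]

DEFAULT_COUNTABLE_RANGE = (1, 200)
DEFAULT_VOLUME_ML = 0.002  # 2 ul spots


class UndefinedEopError(ValueError):
    """EOP requested against a stock that is itself below detection."""


@dataclass
class PlaqueAssay:
    """Spot counts from one dilution series on one host lawn."""

    host_id: str
    spot_counts: list[tuple[float, int]]  # (dilution_factor, plaques)
    plated_volume: float = DEFAULT_VOLUME_ML  # ml per spot
    stock_titer: float | None = None  # PFU/ml, when known

    def __post_init__(self) -> None:
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")
        for d, p in self.spot_counts:
            if d <= 0:
                raise ValueError("dilution factors must be positive")
            if p < 0 or int(p) != p:
                raise ValueError("plaque counts must be non-negative integers")

    @property
    def detection_limit(self) -> float:
        """PFU/ml equivalent of a single plaque at the least-dilute spot."""
        if not self.spot_counts:
            raise ValueError("assay has no spots")
        d_max = max(d for d, _ in self.spot_counts)
        return 1.0 / (d_max * self.plated_volume)


@dataclass(frozen=True)
class TiterResult:
    """Point estimate with a Poisson interval, or a below-detection bound."""

    titer: float | None  # PFU/ml; None when below detection
    ci_low: float | None = None
    ci_high: float | None = None
    below_detection: bool = False
    detection_limit: float | None = None  # PFU/ml upper bound when undetected
    dilution_used: float | None = None


@dataclass(frozen=True)
class EopResult:
    """Efficiency of plaquing; a one-sided upper bound when undetected."""

    eop: float
    below_detection: bool = False

    @property
    def escaper_freq(self) -> float:
        """Alias: for a single-spacer host the EOP is the escape frequency."""
        return self.eop

    def __str__(self) -> str:
        return f"< {self.eop:.3g}" if self.below_detection else f"{self.eop:.3g}"


def titer(
    assay: PlaqueAssay,
    countable_range: tuple[int, int] = DEFAULT_COUNTABLE_RANGE,
    confidence: float = 0.95,
) -> TiterResult:
    """Estimate the stock titer from the most-dilute countable spot.

    A spot is countable when its plaque count falls inside
    *countable_range* (inclusive).  The reported interval is the exact
    (Garwood) Poisson confidence interval for the chosen spot's count,
    scaled to PFU/ml.  When every spot is zero the result is a
    below-detection bound at one plaque in the least-dilute spot.
    """
    lo, hi = countable_range
    countable = [(d, p) for d, p in assay.spot_counts if lo <= p <= hi]
    if not countable:
        if all(p == 0 for _, p in assay.spot_counts):
            return TiterResult(
                titer=None,
                below_detection=True,
                detection_limit=assay.detection_limit,
            )
        raise ValueError(
            f"assay {assay.host_id}: no countable spot in range {countable_range}"
        )
    d, p = min(countable, key=lambda dp: dp[0])  # most dilute countable
    scale = d * assay.plated_volume
    alpha = 1.0 - confidence
    ci_lo = stats.chi2.ppf(alpha / 2.0, 2 * p) / 2.0 if p > 0 else 0.0
    ci_hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * p + 2) / 2.0
    return TiterResult(
        titer=p / scale,
        ci_low=ci_lo / scale,
        ci_high=ci_hi / scale,
        dilution_used=d,
    )


def _as_titer(value: float | TiterResult) -> tuple[float, bool]:
    if isinstance(value, TiterResult):
        if value.below_detection:
            if value.detection_limit is None:
                raise ValueError("below-detection titer carries no limit")
            return value.detection_limit, True
        assert value.titer is not None
        return value.titer, False
    return float(value), False


def eop(test_titer: float | TiterResult, stock_titer: float | TiterResult) -> EopResult:
    """Efficiency of plaquing: test titer over total stock titer.

    Accepts raw PFU/ml values or :class:`TiterResult` objects.  A
    below-detection test propagates as a one-sided upper bound (never
    reported as zero); a below-detection stock makes the EOP undefined.
    """
    stock, stock_bounded = _as_titer(stock_titer)
    if stock_bounded:
        raise UndefinedEopError("stock titer is below detection; EOP undefined")
    if stock <= 0:
        raise UndefinedEopError("stock titer must be positive")
    test, test_bounded = _as_titer(test_titer)
    return EopResult(eop=test / stock, below_detection=test_bounded)


def spike_escapers(stock_pfu: float, current_freq: float, target_freq: float) -> float:
    """PFU of pure escaper stock to add to reach *target_freq*.

    Solves ``(current_freq * stock_pfu + x) / (stock_pfu + x) = target_freq``
    for x, i.e. ``x = stock_pfu * (target_freq - current_freq) / (1 - target_freq)``.
    """
    if stock_pfu <= 0:
        raise ValueError("stock_pfu must be positive")
    if not 0.0 <= current_freq < 1.0 or not 0.0 < target_freq < 1.0:
        raise ValueError("frequencies must lie in [0, 1)")
    if target_freq <= current_freq:
        raise ValueError("target_freq must exceed current_freq (nothing to add)")
    return stock_pfu * (target_freq - current_freq) / (1.0 - target_freq)


def moi(pfu: float, cfu: float) -> float:
    """Multiplicity of infection: phage particles per bacterial cell."""
    if cfu <= 0:
        raise ValueError("cfu must be positive")
    if pfu < 0:
        raise ValueError("pfu must be non-negative")
    return pfu / cfu
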