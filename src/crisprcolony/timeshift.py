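"""Time-shift co-evolution analysis: ordinal resistance scoring and means.

Hosts and phage populations are sampled at labelled time points (hours);
each host lawn is challenged with each phage spot and scored 1 (full
resistance), 0.5 (partial inhibition) or 0 (no resistance).  All three
scores are exactly representable as binary floats, so sums and means over
them are computed without rounding artefacts; missing cells are excluded
from denominators, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCORE_BY_CATEGORY",
    "ResistanceMatrix",
    "Trajectory",
    "UndefinedMeanError",
    "score_observation",
    "mean_resistance",
    "trajectories",
]

SCORE_BY_CATEGORY = {
    "full_resistance": 1.0,
    "partial": 0.5,
    "no_resistance": 0.0,
}

_VALID_SCORES = (0.0, 0.5, 1.0)


class UndefinedMeanError(ValueError):
    """A mean was requested over zero non-missing entries."""


def score_observation(category: str) -> float:
    """Map an observation category to its ordinal score (1 / 0.5 / 0)."""
    try:
        return SCORE_BY_CATEGORY[category]
    except KeyError:
        raise ValueError(
            f"unknown category {category!r}; expected one of {sorted(SCORE_BY_CATEGORY)}"
        ) from None


@dataclass
class ResistanceMatrix:
    """Hosts x phage-populations grid of ordinal scores.

    ``hosts`` and ``phages`` are ``(id, timepoint_hr)`` pairs; time-point 0
    phages are the stock isolates.  ``scores[i, j]`` is the resistance of
    host i against phage j, in {0, 0.5, 1}, with NaN marking missing cells.
    """

    hosts: list[tuple[str, int]]
    phages: list[tuple[str, int]]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.hosts), len(self.phages)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.hosts)} hosts x {len(self.phages)} phages"
            )
        finite = self.scores[~np.isnan(self.scores)]
        if not np.isin(finite, _VALID_SCORES).all():
            raise ValueError("scores must be 0, 0.5, 1 or NaN (missing)")
        if len({h for h, _ in self.hosts}) != len(self.hosts):
            raise ValueError("duplicate host ids")
        if len({p for p, _ in self.phages}) != len(self.phages):
            raise ValueError("duplicate phage ids")

    # -- lookups ---------------------------------------------------------
    def host_index(self, host_id: str) -> int:
        for i, (h, _) in enumerate(self.hosts):
            if h == host_id:
                return i
        raise KeyError(f"unknown host {host_id!r}")

    def host_timepoint(self, host_id: str) -> int:
        return self.hosts[self.host_index(host_id)][1]

    def phage_timepoints(self) -> list[int]:
        return sorted({tp for _, tp in self.phages})

    def phage_columns(self, timepoints: Iterable[int]) -> list[int]:
        tps = set(timepoints)
        return [j for j, (_, tp) in enumerate(self.phages) if tp in tps]

    # -- I/O -------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        """Long-format table: host_id, host_timepoint, phage_id, phage_timepoint, score."""
        rows = []
        for i, (h, htp) in enumerate(self.hosts):
            for j, (p, ptp) in enumerate(self.phages):
                s = self.scores[i, j]
                rows.append((h, htp, p, ptp, None if math.isnan(s) else s))
        return pd.DataFrame(
            rows,
            columns=["host_id", "host_timepoint", "phage_id", "phage_timepoint", "score"],
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ResistanceMatrix":
        """Inverse of :meth:`to_table`; absent (host, phage) rows become NaN."""
        hosts = list(
            table[["host_id", "host_timepoint"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        phages = list(
            table[["phage_id", "phage_timepoint"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        hosts = [(str(h), int(tp)) for h, tp in hosts]
        phages = [(str(p), int(tp)) for p, tp in phages]
        hidx = {h: i for i, (h, _) in enumerate(hosts)}
        pidx = {p: j for j, (p, _) in enumerate(phages)}
        scores = np.full((len(hosts), len(phages)), np.nan)
        for row in table.itertuples(index=False):
            if row.score is not None and not (
                isinstance(row.score, float) and math.isnan(row.score)
            ):
                scores[hidx[str(row.host_id)], pidx[str(row.phage_id)]] = float(row.score)
        return cls(hosts=hosts, phages=phages, scores=scores)


@dataclass(frozen=True)
class Trajectory:
    """Per-host mean resistance against each phage time point."""

    host_id: str
    host_timepoint: int
    means: dict[int, float] = field(default_factory=dict)
    contemporary_score: float | None = None


def mean_resistance(
    matrix: ResistanceMatrix,
    host: str,
    phage_timepoint: int | Iterable[int],
) -> float:
    """Mean score of *host* against all phages of the given time point(s).

    *phage_timepoint* may be a single time point or an iterable (pooled
    average over every phage of those time points).  Missing entries are
    excluded from the denominator.
    """
    i = matrix.host_index(host)
    tps: Sequence[int]
    if isinstance(phage_timepoint, (int, np.integer)):
        tps = [int(phage_timepoint)]
    else:
        tps = [int(t) for t in phage_timepoint]
    cols = matrix.phage_columns(tps)
    if not cols:
        raise UndefinedMeanError(f"no phages at time point(s) {tps}")
    values = matrix.scores[i, cols]
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise UndefinedMeanError(
            f"host {host!r} has no scored entries against time point(s) {tps}"
        )
    return float(values.mean())


def trajectories(matrix: ResistanceMatrix) -> list[Trajectory]:
    """One :class:`Trajectory` per host, ordered by phage time point.

    The contemporary score is the host's mean against phages of its own
    time point (None when no phage shares the host's time point or all
    entries are missing).
    """
    out = []
    ptps = matrix.phage_timepoints()
    for host_id, host_tp in matrix.hosts:
        means: dict[int, float] = {}
        for tp in ptps:
            try:
                means[tp] = mean_resistance(matrix, host_id, tp)
            except UndefinedMeanError:
                continue
        contemporary = means.get(host_tp) if host_tp in ptps else None
        out.append(
            Trajectory(
                host_id=host_id,
                host_timepoint=host_tp,
                means=means,
                contemporary_score=contemporary,
            )
        )
    return out
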