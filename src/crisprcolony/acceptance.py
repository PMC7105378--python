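"""Recomputation helpers for the published-value targets.

Targets t3-t8 recompute text-stated numbers from supplementary source-data
workbooks that accompany the original study.  Those workbooks are not
redistributable here; to run the targets, convert them to TSVs under
``data/source_data/`` with these schemas:

``figure2_source_data1.tsv`` (sequencing of the 26 colonies)
    columns: ``colony_id`` (str), ``read_id`` (str), ``read_count`` (int,
    reads sharing this array), ``spacers`` (comma-joined, leader-proximal
    first).  One row per distinct array per colony.

``figure6_source_data1.tsv`` (time-shift scores)
    long format: ``host_id``, ``host_timepoint``, ``phage_id``,
    ``phage_timepoint``, ``score`` in {0, 0.5, 1}; founder hosts named
    ``founder_F`` and ``founder_C`` at host_timepoint 0.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import timeshift
from .array_parser import SpacerArray, profile_colony

SOURCE_DATA_DIR = Path(__file__).resolve().parents[2] / "data" / "source_data"


def load_fig2_arrays(path: str | Path) -> dict[str, list[tuple[SpacerArray, int]]]:
    """Per-colony lists of ``(array, read_count)`` from the documented TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[tuple[SpacerArray, int]]] = {}
    for row in df.itertuples(index=False):
        spacers = tuple(s for s in str(row.spacers).split(",") if s)
        out.setdefault(str(row.colony_id), []).append(
            (SpacerArray(spacers=spacers, read_id=str(row.read_id)), int(row.read_count))
        )
    return out


def fig2_pair_count(colonies: dict[str, list[tuple[SpacerArray, int]]]) -> int:
    """Number of chronological first-to-second pairs across all colonies.

    One pair per distinct array with >= 2 spacers (pairs are sequence pairs,
    not read copies); no mapping filter is applied here because positions in
    the source table are pre-validated.
    """
    n = 0
    for rows in colonies.values():
        for array, _ in rows:
            if array.n_spacers >= 2:
                n += 1
    return n


def fig2_colony_fractions(
    colonies: dict[str, list[tuple[SpacerArray, int]]],
) -> dict[str, float]:
    """Per-colony multi-spacer READ fractions via ``profile_colony``."""
    fractions = {}
    for colony_id, rows in colonies.items():
        expanded = [array for array, count in rows for _ in range(count)]
        fractions[colony_id] = profile_colony(expanded, colony_id=colony_id).multi_fraction
    return fractions


def load_fig6_matrix(path: str | Path) -> timeshift.ResistanceMatrix:
    return timeshift.ResistanceMatrix.from_table(pd.read_csv(path, sep="\t"))


def fig6_founder_mean(
    matrix: timeshift.ResistanceMatrix,
    founder_id: str,
    final_only: bool = False,
) -> float:
    """Founder mean score against post-infection phage populations.

    Pooled over every phage time point after 0, or only the final one with
    ``final_only`` (the reading used for the founder-C statement).
    """
    post = [tp for tp in matrix.phage_timepoints() if tp > 0]
    if not post:
        raise ValueError("matrix has no post-infection phage time points")
    tps = [post[-1]] if final_only else post
    return timeshift.mean_resistance(matrix, founder_id, tps)
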