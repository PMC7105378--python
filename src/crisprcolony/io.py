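"""Readers and writers for the pipeline's plain-text formats.

Sequence formats go through Biopython; tables are TSV via pandas with the
documented headers below.

- arrays TSV:      read_id, barcode, n_spacers, spacers (comma-joined,
                   leader-proximal first)
- hits TSV:        spacer, start, end, strand, pam, mismatches, ambiguous
- assay TSV:       host_id, dilution_factor, plaques, volume_ml
- timeshift TSV:   host_id, host_timepoint, phage_id, phage_timepoint, score
- config file:     flat ``key=value`` lines, ``#`` comments allowed
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array_parser import ColonyProfile, SpacerArray
from .escape_assay import PlaqueAssay
from .spacer_mapper import ProtospacerHit

DEFAULT_PHRED = 40


# -- sequences -----------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ or FASTA reads as ``(read_id, sequence)``, chosen by extension."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], phred: int = DEFAULT_PHRED) -> None:
    """Write reads with a constant Phred+33 quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [phred] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# -- arrays --------------------------------------------------------------

def write_arrays_tsv(path: str | Path, arrays: Sequence[SpacerArray]) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "barcode": a.barcode if a.barcode is not None else "",
            "n_spacers": a.n_spacers,
            "spacers": ",".join(a.spacers),
        }
        for a in arrays
    ]
    pd.DataFrame(rows, columns=["read_id", "barcode", "n_spacers", "spacers"]).to_csv(
        path, sep="\t", index=False
    )


def read_arrays_tsv(path: str | Path) -> list[SpacerArray]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    arrays = []
    for row in df.itertuples(index=False):
        spacers = tuple(s for s in str(row.spacers).split(",") if s)
        arrays.append(
            SpacerArray(
                spacers=spacers,
                barcode=row.barcode or None,
                read_id=str(row.read_id),
            )
        )
    return arrays


def write_profiles_tsv(path: str | Path, profiles: Sequence[ColonyProfile]) -> None:
    max_n = max((max(p.read_counts_by_n_spacers) for p in profiles), default=0)
    rows = []
    for p in profiles:
        row = {
            "colony_id": p.colony_id,
            "multi_fraction": p.multi_fraction,
            "colony_call": p.colony_call,
            "threshold": p.threshold,
        }
        for n in range(max_n + 1):
            row[f"reads_{n}_spacers"] = p.read_counts_by_n_spacers.get(n, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- hits ----------------------------------------------------------------

def write_hits_tsv(path: str | Path, hits: dict[str, ProtospacerHit | None]) -> None:
    rows = []
    for spacer, hit in hits.items():
        if hit is None:
            rows.append(
                {"spacer": spacer, "start": "", "end": "", "strand": "",
                 "pam": "", "mismatches": "", "ambiguous": ""}
            )
        else:
            rows.append(
                {"spacer": spacer, "start": hit.start, "end": hit.end,
                 "strand": hit.strand, "pam": hit.pam,
                 "mismatches": hit.mismatches, "ambiguous": hit.ambiguous}
            )
    pd.DataFrame(
        rows,
        columns=["spacer", "start", "end", "strand", "pam", "mismatches", "ambiguous"],
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> dict[str, ProtospacerHit | None]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    hits: dict[str, ProtospacerHit | None] = {}
    for row in df.itertuples(index=False):
        if row.start == "":
            hits[row.spacer] = None
        else:
            hits[row.spacer] = ProtospacerHit(
                spacer=row.spacer,
                start=int(row.start),
                strand=row.strand,
                pam=row.pam,
                mismatches=int(row.mismatches),
                ambiguous=str(row.ambiguous) == "True",
            )
    return hits


# -- assays --------------------------------------------------------------

def write_assays_tsv(path: str | Path, assays: Sequence[PlaqueAssay]) -> None:
    rows = [
        {"host_id": a.host_id, "dilution_factor": d, "plaques": p, "volume_ml": a.plated_volume}
        for a in assays
        for d, p in a.spot_counts
    ]
    pd.DataFrame(rows, columns=["host_id", "dilution_factor", "plaques", "volume_ml"]).to_csv(
        path, sep="\t", index=False
    )


def read_assays_tsv(path: str | Path) -> list[PlaqueAssay]:
    df = pd.read_csv(path, sep="\t")
    assays = []
    for host_id, grp in df.groupby("host_id", sort=False):
        volumes = grp["volume_ml"].unique()
        if len(volumes) != 1:
            raise ValueError(f"host {host_id}: inconsistent plated volumes {volumes}")
        assays.append(
            PlaqueAssay(
                host_id=str(host_id),
                spot_counts=[
                    (float(d), int(p))
                    for d, p in zip(grp["dilution_factor"], grp["plaques"])
                ],
                plated_volume=float(volumes[0]),
            )
        )
    return assays


# -- config --------------------------------------------------------------

def write_config(path: str | Path, config) -> None:
    """Write a dataclass config as flat ``key=value`` lines."""
    lines = [
        f"{f.name}={getattr(config, f.name)}" for f in dataclasses.fields(config)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path, cls):
    """Read a ``key=value`` file back into dataclass *cls* (types coerced)."""
    values: dict[str, object] = {}
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in types:
            raise ValueError(f"unknown config key {key!r}")
        t = str(types[key])
        if "int" in t:
            values[key] = int(raw)
        elif "float" in t:
            values[key] = float(raw)
        else:
            values[key] = raw
    return cls(**values)
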