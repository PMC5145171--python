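"""FASTA ingestion and report serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alphabet import (ChemicalAlphabet, EIGHT_GROUPS, EncodedSequence,
                       InvalidResidueError, STANDARD_RESIDUES,
                       encode_sequence)
from .motifs import CommonPatternSet
from .similarity import SimilarityReport

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "encode_records",
    "patternset_to_frame",
    "similarity_to_frame",
    "write_table",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id (first header token), description, residues."""

    seq_id: str
    description: str
    residues: str


def read_fasta(path: str | Path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a (possibly line-wrapped, CRLF-tolerant) FASTA file.

    Sequence ids must be unique; under the strict policy any residue outside
    the 20 standard codes raises :class:`InvalidResidueError` with record and
    1-based offset context.  An empty file is an error.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if policy == "strict":
            for i, r in enumerate(residues):
                if r not in STANDARD_RESIDUES:
                    raise InvalidResidueError(r, position=i + 1,
                                              seq_id=rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(seq_id=rec.id, description=desc,
                                      residues=residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.seq_id
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def encode_records(records: list[SequenceRecord],
                   alphabet: ChemicalAlphabet = EIGHT_GROUPS,
                   policy: str = "strict",
                   seq_range: tuple[int, int] | None = None
                   ) -> list[EncodedSequence]:
    """Encode FASTA records, optionally slicing a 1-based inclusive range.

    ``seq_range=(start, end)`` extracts residues start..end of every record
    before encoding — used to take e.g. an N-terminal head domain of a stated
    length.
    """
    out = []
    for rec in records:
        residues = rec.residues
        if seq_range is not None:
            start, end = seq_range
            if start < 1 or end < start:
                raise ValueError(f"invalid range {start}:{end}")
            residues = residues[start - 1:end]
        out.append(encode_sequence(rec.seq_id, residues, alphabet, policy))
    return out


def patternset_to_frame(cps: CommonPatternSet) -> pd.DataFrame:
    """Flatten a common-pattern set into a tidy hit table.

    Columns: pattern, length, mode, seq_id, position, rendered
    ('position-residues' as in the printed motif tables).  The residue block
    is recoverable from the sequence; the rendering here keeps positions only
    unless hits were located with residues (use motifs.locate_pattern for
    residue blocks).
    """
    rows = []
    for pattern in cps.patterns:
        for seq_id, positions in cps.hits[pattern].items():
            for pos in positions:
                rows.append({"pattern": pattern, "length": cps.length,
                             "mode": cps.mode, "seq_id": seq_id,
                             "position": pos})
    return pd.DataFrame(rows, columns=["pattern", "length", "mode",
                                       "seq_id", "position"])


def similarity_to_frame(reports: list[SimilarityReport]) -> pd.DataFrame:
    """Tidy table of similarity reports, one row per argmax hit."""
    rows = []
    for rep in reports:
        for pos, res, m in rep.hits:
            rows.append({"query_block": rep.query_block,
                         "target_id": rep.target_id,
                         "best_percent": round(rep.best_percent, 2),
                         "position": pos, "residue_block": res,
                         "matches": m, "rendered": f"{pos}-{res}"})
    return pd.DataFrame(rows, columns=["query_block", "target_id",
                                       "best_percent", "position",
                                       "residue_block", "matches",
                                       "rendered"])


def write_table(frame: pd.DataFrame, path: str | Path,
                fmt: str = "tsv") -> None:
    """Serialize a report table as TSV or JSON (records orientation)."""
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'json')")
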