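"""Sequence, label and feature-matrix I/O.

FASTA is the sequence format (parsed with Biopython after a light
structural validation so malformed files fail with a line number); labels
come either from a two-column TSV (id, label) or from the last
'|'-delimited token of each FASTA header; feature matrices round-trip
through TSV with a fixed column schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import PCmerProfile, SCHEME_NAMES

__all__ = [
    "SequenceRecord",
    "LabeledDataset",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "labels_from_headers",
    "attach_labels",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence (upper-case, U already mapped to T)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class LabeledDataset:
    """Records plus one class label per record, in record order."""

    records: list[SequenceRecord]
    labels: list[str]
    level_name: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.records):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA, with the offending line."""


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def _validate_fasta_lines(path: Path) -> None:
    header_line: int | None = None
    body_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not body_seen:
                    raise FastaParseError(
                        f"{path}: entry at line {header_line} has an empty body"
                    )
                header_line = lineno
                body_seen = False
            else:
                if header_line is None:
                    raise FastaParseError(
                        f"{path}: line {lineno} precedes any '>' header"
                    )
                body_seen = True
    if header_line is not None and not body_seen:
        raise FastaParseError(f"{path}: entry at line {header_line} has an empty body")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Residues are upper-cased and U is mapped to T; ambiguity codes are kept
    as-is (encoding decides how to treat them).  An empty file yields an
    empty list; a headerless or body-less entry raises
    :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(SequenceRecord(id=rec.id, residues=_normalize(str(rec.seq))))
    return out


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta-2line")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read the canonical two-column (id, label) TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns, got {df.shape[1]}")
    dupes = df[0][df[0].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate ids in label table: {sorted(set(dupes))}")
    return dict(zip(df[0], df[1]))


def labels_from_headers(records: list[SequenceRecord]) -> dict[str, str]:
    """Fallback mapping: label = last '|'-delimited token of the record id."""
    return {r.id: r.id.rsplit("|", 1)[-1] for r in records}


def attach_labels(
    records: list[SequenceRecord],
    mapping: dict[str, str],
    level_name: str = "",
) -> LabeledDataset:
    """Align a label mapping to record order; extra mapping entries are ignored."""
    missing = [r.id for r in records if r.id not in mapping]
    if missing:
        raise KeyError(f"records missing from label mapping: {missing}")
    return LabeledDataset(
        records=list(records),
        labels=[mapping[r.id] for r in records],
        level_name=level_name,
    )


def _feature_columns(k: int) -> list[str]:
    return [f"{name}_{c}" for name in SCHEME_NAMES for c in range(1, (1 << k) + 1)]


def write_feature_matrix(
    profiles: list[PCmerProfile], ids: list[str], path: str | Path
) -> None:
    """Serialize profiles as TSV: id column then 3 * 2**k feature columns.

    Blocks appear in the fixed scheme order, cells 1..2**k within each
    block; integer counts round-trip bit-exactly through
    :func:`read_feature_matrix`.
    """
    if len(profiles) != len(ids):
        raise ValueError(f"{len(profiles)} profiles but {len(ids)} ids")
    if not profiles:
        raise ValueError("no profiles to write")
    ks = {p.k for p in profiles}
    if len(ks) > 1:
        raise ValueError(f"profiles mix k values: {sorted(ks)}")
    k = ks.pop()
    matrix = np.vstack([p.concat() for p in profiles])
    df = pd.DataFrame(matrix, columns=_feature_columns(k))
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a feature-matrix TSV back; returns (table indexed by id, k)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
    n_features = df.shape[1]
    if n_features % 3:
        raise ValueError(f"{path}: {n_features} feature columns not divisible by 3")
    k = (n_features // 3).bit_length() - 1
    if list(df.columns) != _feature_columns(k):
        raise ValueError(f"{path}: unexpected feature column schema")
    return df, k
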