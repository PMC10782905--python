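"""Sequence, label-track and paired-dataset I/O.

Protein sequences travel as FASTA; per-residue binding annotations travel as a
FASTA-like parallel text file (``>id`` header followed by one '0'/'1' character
per residue).  Records and label tracks are joined by exact id string; an
unmatched id is an error, never a silent drop.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 canonical amino acids plus 'X' for unknown/non-canonical residues.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHABET_SET = frozenset(ALPHABET)


class SequenceIOError(ValueError):
    """Malformed sequence, label track or dataset pairing."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("protein record id must be non-empty")
        if not self.sequence:
            raise SequenceIOError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise SequenceIOError(
                f"record {self.id!r} contains letters outside {ALPHABET!r}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabelTrack:
    """Per-residue binary annotation: 1 = binding residue, 0 = non-binding."""

    id: str
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("label track id must be non-empty")
        if len(self.labels) == 0:
            raise SequenceIOError(f"label track {self.id!r} is empty")
        for pos, v in enumerate(self.labels, start=1):
            if v not in (0, 1):
                raise SequenceIOError(
                    f"label track {self.id!r}: invalid label {v!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return sum(self.labels)


@dataclass
class LabeledDataset:
    """Protein records paired one-to-one with label tracks by id."""

    records: list[ProteinRecord]
    labels: list[LabelTrack]
    _by_id: dict[str, tuple[ProteinRecord, LabelTrack]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        rec_ids = [r.id for r in self.records]
        lab_ids = [t.id for t in self.labels]
        if len(set(rec_ids)) != len(rec_ids):
            raise SequenceIOError("duplicate record ids in dataset")
        if set(rec_ids) != set(lab_ids):
            missing = set(rec_ids) ^ set(lab_ids)
            raise SequenceIOError(f"record/label id mismatch: {sorted(missing)}")
        tracks = {t.id: t for t in self.labels}
        for rec in self.records:
            track = tracks[rec.id]
            if len(track) != len(rec):
                raise SequenceIOError(
                    f"record {rec.id!r}: sequence length {len(rec)} != "
                    f"label length {len(track)}"
                )
            self._by_id[rec.id] = (rec, track)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> tuple[ProteinRecord, LabelTrack]:
        return self._by_id[rec_id]

    def __iter__(self):
        return iter(self._by_id.values())


@dataclass(frozen=True)
class DatasetStats:
    n_proteins: int
    n_pos: int
    n_neg: int
    pct_pos: float


def _sanitize_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    out = []
    for pos, ch in enumerate(seq, start=1):
        if ch in _ALPHABET_SET:
            out.append(ch)
        else:
            logger.warning(
                "record %r: non-canonical residue %r at position %d mapped to 'X'",
                rec_id, ch, pos,
            )
            warnings.warn(
                f"record {rec_id!r}: non-canonical residue {ch!r} at position "
                f"{pos} mapped to 'X'",
                stacklevel=3,
            )
            out.append("X")
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; letters outside the 21-letter alphabet
    (20 canonical + 'X') are mapped to 'X' with a warning.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if len(rec.seq) == 0:
                raise SequenceIOError(f"{path}: header {rec.id!r} has an empty sequence")
            records.append(ProteinRecord(rec.id, _sanitize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise SequenceIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as single-line-sequence FASTA (byte-exact round trip)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta-2line")


def read_labels(path: str | Path) -> list[LabelTrack]:
    """Read label tracks from a FASTA-like file of '>id' headers and 0/1 lines."""
    path = Path(path)
    tracks: list[LabelTrack] = []
    cur_id: str | None = None
    cur: list[int] = []

    def flush() -> None:
        nonlocal cur_id, cur
        if cur_id is not None:
            if not cur:
                raise SequenceIOError(f"{path}: header {cur_id!r} has no labels")
            tracks.append(LabelTrack(cur_id, tuple(cur)))
        cur_id, cur = None, []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise SequenceIOError(f"{path}:{lineno}: empty label-track id")
            else:
                if cur_id is None:
                    raise SequenceIOError(f"{path}:{lineno}: labels before any '>' header")
                for ch in line:
                    if ch not in "01":
                        raise SequenceIOError(
                            f"{path}: track {cur_id!r}: invalid character {ch!r} "
                            f"at position {len(cur) + 1}"
                        )
                    cur.append(int(ch))
    flush()
    if not tracks:
        raise SequenceIOError(f"{path}: no label tracks found")
    return tracks


def write_labels(tracks: Iterable[LabelTrack], path: str | Path) -> None:
    with open(path, "w") as handle:
        for t in tracks:
            handle.write(f">{t.id}\n")
            handle.write("".join(str(v) for v in t.labels) + "\n")


def dataset_stats(ds: LabeledDataset) -> DatasetStats:
    """Residue-level counts and the positive percentage (2 decimals).

    pct_pos = 100 * n_pos / (n_pos + n_neg).
    """
    if len(ds) == 0:
        raise SequenceIOError("empty dataset")
    n_pos = sum(t.n_positive for t in ds.labels)
    n_total = sum(len(t) for t in ds.labels)
    if n_total == 0:
        raise SequenceIOError("dataset contains zero residues")
    return DatasetStats(
        n_proteins=len(ds),
        n_pos=n_pos,
        n_neg=n_total - n_pos,
        pct_pos=round(100.0 * n_pos / n_total, 2),
    )


def load_dataset(fasta_path: str | Path, labels_path: str | Path) -> LabeledDataset:
    """Read and pair a FASTA file with its parallel label file."""
    return LabeledDataset(read_fasta(fasta_path), read_labels(labels_path))
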