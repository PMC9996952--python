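"""Sequence primitives, transcriptome container and FASTA/TSV I/O.

Conventions used throughout the package:

* all coordinates are 0-based, half-open; reports additionally print
  1-based inclusive coordinates for human reading;
* input sequences are normalized to the DNA alphabet: ``U`` is mapped to
  ``T`` and case is folded to upper. Only ``A/C/G/T/N`` survive
  normalization, anything else is an :class:`~oligoblock.errors.InputError`;
* ``N`` is allowed in transcriptome sequences (where it conservatively
  mismatches candidate oligo bases during screening) but not in designed
  oligos.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and validate the alphabet.

    Raises :class:`InputError` naming the first offending position.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in VALID_BASES:
            raise InputError(
                f"{context}: invalid nucleotide {ch!r} at position {i} "
                f"(0-based; 1-based {i + 1})"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the A/C/G/T/N alphabet.

    ``N`` maps to ``N``. The empty string maps to itself.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in VALID_BASES:
            raise InputError(
                f"reverse_complement: invalid nucleotide {ch!r} at position {i}"
            )
    return s.translate(_COMPLEMENT)[::-1]


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise InputError(
            f"hamming_distance: unequal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Interval:
    """Half-open interval on the sense strand of one transcript.

    Blocking oligos always bind antisense to the sense transcript, so no
    per-interval strand field is carried beyond ``strand_of_oligo``.
    """

    transcript_id: str
    start: int
    end: int
    strand_of_oligo: str = "antisense"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"Interval on {self.transcript_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand_of_oligo != "antisense":
            raise InputError("strand_of_oligo must be 'antisense'")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.transcript_id == other.transcript_id
            and self.start < other.end
            and other.start < self.end
        )

    def one_based(self) -> Tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


@dataclass
class TranscriptRecord:
    id: str
    seq: str
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("transcript id must be non-empty")
        if not self.seq:
            raise InputError(f"transcript {self.id!r}: empty sequence")
        self.seq = normalize_sequence(self.seq, context=f"transcript {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


class Transcriptome:
    """Ordered collection of transcripts with id lookup and an optional
    exact k-mer index.

    The index is a pure acceleration structure: indexed and non-indexed
    queries return identical results.
    """

    def __init__(self, records: Optional[List[TranscriptRecord]] = None):
        self._records: List[TranscriptRecord] = []
        self._by_id: Dict[str, TranscriptRecord] = {}
        self._kmer_index: Optional[Dict[str, List[Tuple[str, int]]]] = None
        self._index_k: Optional[int] = None
        for rec in records or []:
            self.add(rec)

    def add(self, record: TranscriptRecord) -> None:
        if record.id in self._by_id:
            raise InputError(f"duplicate transcript id: {record.id!r}")
        self._records.append(record)
        self._by_id[record.id] = record
        self._kmer_index = None  # invalidate

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TranscriptRecord]:
        return iter(self._records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def get(self, transcript_id: str, *, use_index: bool = True) -> TranscriptRecord:
        if use_index:
            try:
                return self._by_id[transcript_id]
            except KeyError:
                raise InputError(f"unknown transcript id: {transcript_id!r}") from None
        for rec in self._records:  # linear-scan reference path
            if rec.id == transcript_id:
                return rec
        raise InputError(f"unknown transcript id: {transcript_id!r}")

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self._records]

    def build_index(self, k: int) -> None:
        """Build an exact k-mer position index (lookup acceleration only)."""
        index: Dict[str, List[Tuple[str, int]]] = {}
        for rec in self._records:
            seq = rec.seq
            for pos in range(len(seq) - k + 1):
                index.setdefault(seq[pos : pos + k], []).append((rec.id, pos))
        self._kmer_index = index
        self._index_k = k

    def find_exact(self, kmer: str, *, use_index: Optional[bool] = None) -> List[Tuple[str, int]]:
        """All (transcript_id, start) positions of an exact k-mer match.

        Results are sorted by (transcript order, position) and identical
        whether or not the index is used.
        """
        if use_index is None:
            use_index = self._kmer_index is not None and self._index_k == len(kmer)
        if use_index and self._kmer_index is not None and self._index_k == len(kmer):
            return list(self._kmer_index.get(kmer, []))
        hits: List[Tuple[str, int]] = []
        k = len(kmer)
        for rec in self._records:
            start = rec.seq.find(kmer)
            while start != -1:
                hits.append((rec.id, start))
                start = rec.seq.find(kmer, start + 1)
        return hits

    def attach_biotypes(self, biotype_map: Dict[str, str]) -> None:
        for rec in self._records:
            if rec.id in biotype_map:
                rec.biotype = biotype_map[rec.id]


def read_fasta(path: str | Path) -> Transcriptome:
    """Read a (possibly line-wrapped) FASTA file.

    The header token before the first whitespace is the record id. U is
    normalized to T and case folded to upper. Duplicate ids and empty
    sequences are errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    tx = Transcriptome()
    seen_dupes: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in tx:
            seen_dupes.append(rec.id)
            continue
        if len(rec.seq) == 0:
            raise InputError(f"{path}: record {rec.id!r} has an empty sequence")
        tx.add(TranscriptRecord(id=rec.id, seq=str(rec.seq)))
    if seen_dupes:
        raise InputError(f"{path}: duplicate transcript ids: {sorted(set(seen_dupes))}")
    return tx


def write_fasta(transcriptome: Transcriptome, path: str | Path, *, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(rec.seq), id=rec.id, description="")
        for rec in transcriptome
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_biotype_table(path: str | Path) -> Dict[str, str]:
    """Two-column TSV ``transcript_id<TAB>biotype`` with optional header."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"biotype table not found: {path}")
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            tid, biotype = parts[0], parts[1]
            if lineno == 1 and tid.lower() in {"transcript_id", "id", "transcript"}:
                continue  # header row
            mapping[tid] = biotype
    return mapping
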