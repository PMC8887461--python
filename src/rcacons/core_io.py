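"""Domain types and readers/writers for FASTQ, FASTA and the per-read report.

Sequences are stored uppercase over {A,C,G,T,N}; RNA input (``U``) is
converted to ``T`` on ingestion so adaptor oligos (RNA) and basecalled
reads (cDNA) share one alphabet.  Per-base qualities are carried through
I/O but never consulted downstream: the consensus caller corrects errors
with repeat redundancy, not base qualities.  All coordinates anywhere in
the package are 0-based half-open on the read as stored in the FASTQ.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PathLike = Union[str, Path]

_ALPHABET = frozenset("ACGTN")

#: Exact column order of the per-read report CSV.
REPORT_COLUMNS = [
    "read_id",
    "parent_read_id",
    "read_length",
    "read_class",
    "n_adaptors",
    "n_inserts_detected",
    "n_inserts_used",
    "mean_insert_identity",
    "consensus_length",
    "status",
    "discard_reason",
]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class SequenceRecord:
    """One read or reference sequence with optional per-base quality."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = _normalize(self.sequence)
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Adaptor:
    """A circAID or sequencing adaptor in its cDNA (DNA) representation."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = _normalize(self.sequence)
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"adaptor {self.name!r}: invalid characters {sorted(bad)}")
        if len(self.sequence) < 12:
            raise ValueError(
                f"adaptor {self.name!r} is {len(self.sequence)} nt; "
                "adaptors shorter than 12 nt cannot be detected reliably"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FilterConfig:
    """Per-read acceptance thresholds.

    Defaults are the Ribo-seq settings: >=3 inserts, >=4 adaptors,
    consensus >=20 nt, insert length within [15, 40] nt, and 0.70 minimum
    identity both for accepting an adaptor hit and for keeping an insert
    row in the MSA.
    """

    min_inserts: int = 3
    min_adaptors: int = 4
    min_consensus_len: int = 20
    insert_len_min: int = 15
    insert_len_max: int = 40
    adaptor_identity_min: float = 0.70
    insert_identity_min: float = 0.70

    def __post_init__(self) -> None:
        if not (0 < self.insert_len_min <= self.insert_len_max):
            raise ValueError("require 0 < insert_len_min <= insert_len_max")
        for name in ("adaptor_identity_min", "insert_identity_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _open_text(path: PathLike):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _infer_format(path: PathLike) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}; pass format explicitly")


def read_sequences(path: PathLike, format: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA/FASTQ file (gzip autodetected by extension).

    Malformed records raise ``ValueError`` naming the 1-based record
    ordinal.  Sequences are normalised (uppercase, U->T) on the fly.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    with _open_text(path) as fh:
        parser = FastqGeneralIterator(fh) if fmt == "fastq" else SimpleFastaParser(fh)
        ordinal = 0
        while True:
            ordinal += 1
            try:
                item = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed {fmt} record {ordinal} in {path}: {exc}"
                ) from exc
            try:
                if fmt == "fastq":
                    title, seq, qual = item
                    yield SequenceRecord(title.split()[0], seq, qual)
                else:
                    title, seq = item
                    yield SequenceRecord(title.split()[0], seq)
            except ValueError as exc:
                raise ValueError(
                    f"malformed {fmt} record {ordinal} in {path}: {exc}"
                ) from exc


def read_adaptors(path: PathLike) -> list[Adaptor]:
    """Load adaptor oligos from a FASTA file."""
    return [Adaptor(rec.id, rec.sequence) for rec in read_sequences(path, "fasta")]


def _fasta_record(rec_id: str, seq: str, description: str = "") -> _BioSeqRecord:
    return _BioSeqRecord(Seq(seq), id=rec_id, description=description)


def report_frame(records: Iterable) -> pd.DataFrame:
    """Per-read report as a DataFrame with the canonical column order."""
    rows = []
    for rec in records:
        rows.append(
            {
                "read_id": rec.read_id,
                "parent_read_id": rec.parent_read_id,
                "read_length": rec.read_length,
                "read_class": rec.read_class,
                "n_adaptors": rec.n_adaptors,
                "n_inserts_detected": rec.n_inserts_detected,
                "n_inserts_used": rec.n_inserts_used,
                "mean_insert_identity": round(rec.mean_insert_identity, 4),
                "consensus_length": len(rec.consensus),
                "status": rec.status,
                "discard_reason": rec.discard_reason,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_outputs(records: Iterable, out_dir: PathLike) -> dict[str, Path]:
    """Write consensus FASTA, discarded FASTA and report CSV.

    Pass records contribute their consensus sequence to ``consensus.fasta``;
    discarded records contribute the read-unit sequence to
    ``discarded.fasta`` with the exclusion reason tagged in the header as
    ``reason=<tag>``.  Output bytes are identical across runs on identical
    input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = list(records)
    paths = {
        "consensus": out / "consensus.fasta",
        "discarded": out / "discarded.fasta",
        "report": out / "report.csv",
    }
    passing = [r for r in records if r.status == "pass"]
    discarded = [r for r in records if r.status != "pass"]
    SeqIO.write(
        [_fasta_record(f"{r.read_id}", r.consensus, f"class={r.read_class}") for r in passing],
        paths["consensus"],
        "fasta",
    )
    SeqIO.write(
        [
            _fasta_record(r.read_id, r.read_sequence, f"reason={r.discard_reason}")
            for r in discarded
        ],
        paths["discarded"],
        "fasta",
    )
    report_frame(records).to_csv(paths["report"], index=False, lineterminator="\n")
    return paths


def write_counts(counts: dict[str, int], path: PathLike) -> None:
    """Counts TSV: reference_id, count (input key order preserved)."""
    pd.DataFrame(
        {"reference_id": list(counts), "count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
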