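"""Synthetic rolling-circle concatemer reads with ground truth.

The generator emulates what the pipeline sees after basecalling: long
reads made of tandem (adaptor + insert) repeats, in four artifact classes
(forward, reverse, fused, hairpin), corrupted by an independent per-base
substitution/insertion/deletion error model.  Every read comes with a
truth record (insert, repeat count, class) so classification, consensus
accuracy and quantification can all be scored exactly.

Defaults encode the study conditions: read lengths ~ Normal(550, 80) nt
(the read-length peak of RT processivity), a 24-nt adaptor, 10% total
error (5% substitutions, 2.5% insertions, 2.5% deletions — an R9.4-era
basecalling figure), and class fractions forward 0.20 / reverse 0.55 /
fused 0.10 / hairpin 0.15.

Simplifications (see docs/methods.md): reads contain whole repeat units
only — the error model, not the generator, produces ragged ends — and a
fused read joins two molecules carrying the same insert, so each read has
a single true insert.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import reverse_complement
from .core_io import Adaptor, PathLike, SequenceRecord

#: Synthetic 24-nt ligation adaptor used by default throughout.
DEFAULT_ADAPTOR = Adaptor("ADR24", "ATCGTAGGCTGATCAAGCTCCGTA")

#: Synthetic 30-nt sequencing-adaptor stand-in left at fusion junctions.
DEFAULT_REMNANT = Adaptor("SEQADPT", "GGTTACCGTGCAATACCAGTCGGATTCTAG")

DEFAULT_CLASS_FRACTIONS = {"forward": 0.20, "reverse": 0.55, "fused": 0.10, "hairpin": 0.15}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base error probabilities."""

    sub_rate: float = 0.05
    ins_rate: float = 0.025
    del_rate: float = 0.025

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must be >=0 and sum to <1")


@dataclass
class SimParams:
    """Generative-model parameters for one simulated library."""

    inserts: list[tuple[SequenceRecord, float]]
    adaptor: Adaptor = field(default_factory=lambda: DEFAULT_ADAPTOR)
    remnant: Adaptor = field(default_factory=lambda: DEFAULT_REMNANT)
    n_reads: int = 1000
    read_len_mean: float = 550.0
    read_len_sd: float = 80.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    error_model: ErrorModel = field(default_factory=ErrorModel)
    min_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inserts:
            raise ValueError("at least one insert is required")
        if any(w <= 0 for _, w in self.inserts):
            raise ValueError("insert abundances must be positive")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    true_insert_name: str
    true_repeat_count: int
    true_class: str
    true_consensus: str


def random_insert(length: int, rng: np.random.Generator, name: str = "insert") -> SequenceRecord:
    """A uniform-random DNA insert of the given length."""
    seq = bytes(_BASES[rng.integers(0, 4, length)]).decode()
    return SequenceRecord(name, seq)


def make_clean_concatemer(insert: str, adaptor: str, n_repeats: int) -> str:
    """(adaptor + insert) repeated ``n_repeats`` times, error-free."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    return (adaptor + insert) * n_repeats


def corrupt(seq: str, error_model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply independent per-base substitution, insertion and deletion.

    Expected output length is ``len(seq) * (1 + ins_rate - del_rate)``.
    Substitutions draw uniformly from the three alternative bases;
    insertions add a uniform base after the position.
    """
    if not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    keep = rng.random(n) >= error_model.del_rate
    sub = rng.random(n) < error_model.sub_rate
    offsets = rng.integers(1, 4, n)
    ins = rng.random(n) < error_model.ins_rate
    ins_codes = _BASES[rng.integers(0, 4, n)]
    idx = _IDX[arr]
    new = _BASES[(idx % 4 + offsets) % 4]  # N (idx 4) substitutes pseudo-uniformly
    cur = np.where(sub, new, arr)
    counts = keep.astype(np.int64) + ins
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    off = np.cumsum(counts) - counts
    out[off[keep]] = cur[keep]
    out[(off + keep)[ins]] = ins_codes[ins]
    return out.tobytes().decode()


def _concatemer_units(unit: str, target_len: int, min_units: int) -> tuple[str, int]:
    n = max(min_units, int(round(target_len / len(unit))))
    return unit * n, n


def make_read(
    params: SimParams,
    rng: np.random.Generator,
    read_index: int = 0,
) -> tuple[SequenceRecord, TruthRecord]:
    """Draw one read and its truth record.

    Reads are whole numbers of repeat units; forward reads are truncated
    (fragmented second-strand copies, length factor U(0.3, 0.8), floor two
    units so they stay classifiable); reverse reads are the reverse
    complement of the clean concatemer; hairpin reads append the reverse
    complement of their first half with no junction sequence; fused reads
    join two molecules around a sequencing-adaptor remnant.
    """
    weights = np.array([w for _, w in params.inserts], dtype=float)
    insert_rec, _ = params.inserts[int(rng.choice(len(params.inserts), p=weights / weights.sum()))]
    classes = list(params.class_fractions)
    fractions = np.array([params.class_fractions[c] for c in classes], dtype=float)
    read_class = classes[int(rng.choice(len(classes), p=fractions / fractions.sum()))]
    unit = params.adaptor.sequence + insert_rec.sequence
    target = max(
        len(unit) * max(params.min_repeats, 1),
        int(round(rng.normal(params.read_len_mean, params.read_len_sd))),
    )
    min_units = max(params.min_repeats, 2)
    if read_class == "forward":
        clean, n = _concatemer_units(unit, target, min_units)
        frac = rng.uniform(0.3, 0.8)
        n = max(min_units, int(round(n * frac)))
        seq = unit * n
        repeats = n
    elif read_class == "reverse":
        clean, n = _concatemer_units(unit, target, min_units)
        seq = reverse_complement(clean)
        repeats = n
    elif read_class == "hairpin":
        half, n = _concatemer_units(unit, target // 2, max(params.min_repeats, 1))
        seq = reverse_complement(half) + half
        repeats = 2 * n
    elif read_class == "fused":
        half1, n1 = _concatemer_units(unit, target // 2, max(params.min_repeats, 1))
        half2, n2 = _concatemer_units(unit, target // 2, max(params.min_repeats, 1))
        seq = reverse_complement(half1) + params.remnant.sequence + half2
        repeats = n1 + n2
    else:
        raise ValueError(f"unknown read class {read_class!r}")
    noisy = corrupt(seq, params.error_model, rng)
    if not noisy:  # vanishingly unlikely; keep the record well-formed
        noisy = "A"
    read_id = f"sim{read_index:06d}"
    record = SequenceRecord(read_id, noisy, "I" * len(noisy))
    truth = TruthRecord(read_id, insert_rec.id, repeats, read_class, insert_rec.sequence)
    return record, truth


def simulate_reads(params: SimParams) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate the whole library in memory, reproducibly from the seed."""
    rng = np.random.default_rng(params.seed)
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    for i in range(params.n_reads):
        rec, truth = make_read(params, rng, i)
        records.append(rec)
        truths.append(truth)
    return records, truths


def simulate_library(
    params: SimParams,
    fastq_path: PathLike,
    truth_path: PathLike,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Write the library to FASTQ plus a truth CSV; byte-reproducible."""
    records, truths = simulate_reads(params)
    with open(fastq_path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
    pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "insert_name": [t.true_insert_name for t in truths],
            "repeat_count": [t.true_repeat_count for t in truths],
            "class": [t.true_class for t in truths],
            "insert_sequence": [t.true_consensus for t in truths],
        }
    ).to_csv(truth_path, index=False, lineterminator="\n")
    return records, truths


def params_from_json(path: PathLike) -> SimParams:
    """Load SimParams from a JSON config mirroring the dataclass fields."""
    with open(path) as fh:
        raw = json.load(fh)
    inserts = [
        (SequenceRecord(d["name"], d["sequence"]), float(d.get("abundance", 1.0)))
        for d in raw["inserts"]
    ]
    kwargs = {}
    if "adaptor" in raw:
        kwargs["adaptor"] = Adaptor(raw["adaptor"]["name"], raw["adaptor"]["sequence"])
    if "remnant" in raw:
        kwargs["remnant"] = Adaptor(raw["remnant"]["name"], raw["remnant"]["sequence"])
    if "error_model" in raw:
        kwargs["error_model"] = ErrorModel(**raw["error_model"])
    for key in ("n_reads", "read_len_mean", "read_len_sd", "class_fractions", "min_repeats", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return SimParams(inserts=inserts, **kwargs)


def params_to_json(params: SimParams, path: PathLike) -> None:
    """Serialise SimParams to a JSON config readable by params_from_json."""
    raw = {
        "inserts": [
            {"name": rec.id, "sequence": rec.sequence, "abundance": w}
            for rec, w in params.inserts
        ],
        "adaptor": {"name": params.adaptor.name, "sequence": params.adaptor.sequence},
        "remnant": {"name": params.remnant.name, "sequence": params.remnant.sequence},
        "error_model": asdict(params.error_model),
        "n_reads": params.n_reads,
        "read_len_mean": params.read_len_mean,
        "read_len_sd": params.read_len_sd,
        "class_fractions": params.class_fractions,
        "min_repeats": params.min_repeats,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)
        fh.write("\n")
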