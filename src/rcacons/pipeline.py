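"""End-to-end orchestration: reads in, consensus + report out.

Per read: detect sequencing-adaptor remnants, scan ligation-adaptor
copies, classify the artifact, split fused reads (children are processed
independently and keep ``parent/<k>`` ids), extract inserts, two-pass MSA
with low-identity row removal, plurality consensus, then the QC filters.
Everything is deterministic, so two runs on the same inputs produce
byte-identical output files.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    ReadAnnotation,
    annotate_read,
    classify_read,
    detect_remnants,
    scan_adaptors,
    split_fused,
)
from .consensus import (
    LowQualityInsertsError,
    build_msa,
    call_consensus,
    extract_inserts,
    filter_inserts,
    pairwise_identity_profile,
)
from .core_io import (
    Adaptor,
    FilterConfig,
    PathLike,
    SequenceRecord,
    read_adaptors,
    read_sequences,
    write_counts,
    write_outputs,
)
from .report import (
    ConsensusRecord,
    apply_filters,
    quantify,
    read_accuracy,
    recovery_fit,
)

logger = logging.getLogger("rcacons")


@dataclass
class RunConfig:
    """File-level configuration for one pipeline run."""

    reads: Path
    adaptors: Path
    out_dir: Path
    remnants: Optional[Path] = None
    references: Optional[Path] = None
    proportions: Optional[list[float]] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    fit_scale: str = "log"

    def __post_init__(self) -> None:
        for attr in ("reads", "adaptors", "remnants", "references"):
            value = getattr(self, attr)
            if value is not None:
                path = Path(value)
                if not path.exists():
                    raise FileNotFoundError(f"{attr} file not found: {path}")
                setattr(self, attr, path)
        self.out_dir = Path(self.out_dir)


def _process_unit(
    read: SequenceRecord,
    annotation: ReadAnnotation,
    config: FilterConfig,
    parent_id: str,
) -> ConsensusRecord:
    inserts = extract_inserts(read, annotation, config)
    consensus = ""
    n_used = 0
    mean_identity = 0.0
    if len(inserts) >= 2:
        msa = build_msa(inserts)
        profile = pairwise_identity_profile(msa)
        try:
            msa2 = filter_inserts(msa, profile, config)
        except LowQualityInsertsError:
            n_used = sum(1 for p in profile if p >= config.insert_identity_min)
        else:
            profile2 = pairwise_identity_profile(msa2)
            consensus = call_consensus(msa2)
            n_used = len(msa2.rows)
            mean_identity = float(np.mean(profile2))
    candidate = ConsensusRecord(
        read_id=read.id,
        parent_read_id=parent_id,
        read_sequence=read.sequence,
        consensus=consensus,
        read_length=len(read.sequence),
        read_class=annotation.read_class,
        n_adaptors=len(annotation.hits),
        n_inserts_detected=len(inserts),
        n_inserts_used=n_used,
        mean_insert_identity=mean_identity,
    )
    return apply_filters(candidate, config)


def process_read(
    read: SequenceRecord,
    adaptors: Sequence[Adaptor],
    remnant_adaptors: Sequence[Adaptor],
    config: FilterConfig,
) -> list[ConsensusRecord]:
    """Annotate, (maybe) split, and call consensus for one input read."""
    annotation = annotate_read(read, adaptors, remnant_adaptors, config)
    if annotation.read_class != "fused":
        return [_process_unit(read, annotation, config, read.id)]
    out = []
    for child in split_fused(read, annotation):
        child_remnants = detect_remnants(
            child, remnant_adaptors, config.adaptor_identity_min
        )
        child_hits = scan_adaptors(child, adaptors, config)
        child_ann = classify_read(child_hits, child_remnants, child)
        out.append(_process_unit(child, child_ann, config, read.id))
    return out


def process_library(
    reads: Iterable[SequenceRecord],
    adaptors: Sequence[Adaptor],
    remnant_adaptors: Sequence[Adaptor] = (),
    config: Optional[FilterConfig] = None,
) -> list[ConsensusRecord]:
    """Run the full pipeline over an in-memory library."""
    config = config or FilterConfig()
    records: list[ConsensusRecord] = []
    for read in reads:
        records.extend(process_read(read, adaptors, remnant_adaptors, config))
    return records


def run(config: RunConfig) -> dict:
    """File-based pipeline run; writes outputs and returns a summary dict."""
    adaptors = read_adaptors(config.adaptors)
    remnants = read_adaptors(config.remnants) if config.remnants else []
    reads = list(read_sequences(config.reads))
    if not reads:
        logger.warning("no usable reads in %s; writing empty outputs", config.reads)
    records = process_library(reads, adaptors, remnants, config.filters)
    paths = write_outputs(records, config.out_dir)
    tallies = Counter(r.discard_reason for r in records if r.status != "pass")
    n_pass = sum(1 for r in records if r.status == "pass")
    logger.info("reads in: %d; read units: %d; pass: %d", len(reads), len(records), n_pass)
    for reason, n in sorted(tallies.items()):
        logger.info("discarded %-20s %d", reason, n)
    summary = {
        "n_reads": len(reads),
        "n_units": len(records),
        "n_pass": n_pass,
        "discards": dict(tallies),
        "paths": {k: str(v) for k, v in paths.items()},
    }
    if config.references:
        references = list(read_sequences(config.references))
        counts = quantify(records, references)
        write_counts(counts, config.out_dir / "counts.tsv")
        summary["counts"] = counts
        accuracy_rows = []
        for rec in records:
            if rec.status != "pass":
                continue
            best_ref = max(
                references,
                key=lambda ref: read_accuracy(rec.consensus, ref.sequence).accuracy_pct,
            )
            acc = read_accuracy(rec.consensus, best_ref.sequence)
            accuracy_rows.append(
                {
                    "read_id": rec.read_id,
                    "reference_id": best_ref.id,
                    "read_length": acc.read_length,
                    "n_mismatches": acc.n_mismatches,
                    "n_indels": acc.n_indels,
                    "accuracy_pct": round(acc.accuracy_pct, 4),
                }
            )
        pd.DataFrame(
            accuracy_rows,
            columns=[
                "read_id",
                "reference_id",
                "read_length",
                "n_mismatches",
                "n_indels",
                "accuracy_pct",
            ],
        ).to_csv(config.out_dir / "accuracy.csv", index=False, lineterminator="\n")
        if accuracy_rows:
            summary["median_accuracy_pct"] = float(
                np.median([r["accuracy_pct"] for r in accuracy_rows])
            )
        if config.proportions:
            props = np.asarray(config.proportions, dtype=float)
            props = props / props.sum()
            proportions = {ref.id: p for ref, p in zip(references, props)}
            summary["recovery_r2"] = recovery_fit(counts, proportions, config.fit_scale)
    return summary
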