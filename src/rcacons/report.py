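"""Per-read QC filters, the read-accuracy metric, and quantification.

A read (or fused-read child) passes when it clears, in order: at least one
adaptor, enough adaptors, enough detected inserts, enough inserts
surviving the identity filter, and a long-enough consensus.  The first
failing rule becomes the single discard reason, so every discarded read
carries exactly one tag.

Accuracy follows the concatemer-consensus convention: the fraction of the
aligned consensus not altered by mismatches or indels,

    accuracy = (L - (mismatches + indels)) / L * 100

with L the number of alignment columns against the reference.

Quantification counts only reverse and hairpin reads: forward strands are
fragmented second-strand copies and would bias abundance estimates.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .align import Scoring, global_align, reverse_complement

#: Scoring under which the maximal-score global alignment is exactly a
#: minimum-edit-distance alignment (score == -edit_distance).
EDIT_SCORING = Scoring(match=0, mismatch=-1, gap=-1)
from .core_io import FilterConfig, SequenceRecord

DISCARD_REASONS = (
    "no_adaptor",
    "too_few_adaptors",
    "too_few_inserts",
    "low_quality_inserts",
    "consensus_too_short",
    "unclassified",
)

#: Minimum consensus-to-reference identity for abundance assignment.
DEFAULT_ASSIGN_IDENTITY = 0.80


@dataclass
class ConsensusRecord:
    """Per-read consensus with QC statistics and pass/discard status."""

    read_id: str
    parent_read_id: str
    read_sequence: str
    consensus: str
    read_length: int
    read_class: str
    n_adaptors: int
    n_inserts_detected: int
    n_inserts_used: int
    mean_insert_identity: float
    status: str = ""
    discard_reason: str = ""


@dataclass(frozen=True)
class AccuracyResult:
    """Counts and percentage from one consensus-to-reference alignment."""

    read_length: int
    n_mismatches: int
    n_indels: int
    accuracy_pct: float


def apply_filters(candidate: ConsensusRecord, config: FilterConfig) -> ConsensusRecord:
    """Set status/discard_reason by the first failing rule, in fixed order."""
    reason = ""
    if candidate.n_adaptors == 0:
        reason = "no_adaptor"
    elif candidate.n_adaptors < config.min_adaptors:
        reason = "too_few_adaptors"
    elif candidate.n_inserts_detected < config.min_inserts:
        reason = "too_few_inserts"
    elif candidate.n_inserts_used < config.min_inserts:
        reason = "low_quality_inserts"
    elif len(candidate.consensus) < config.min_consensus_len:
        reason = "consensus_too_short"
    elif candidate.read_class == "unclassified":
        reason = "unclassified"
    if reason:
        return replace(candidate, status="discard", discard_reason=reason)
    return replace(candidate, status="pass", discard_reason="")


def read_accuracy(consensus: str, reference: str) -> AccuracyResult:
    """Read accuracy of a consensus against its reference, in percent.

    Counts come from a minimum-edit global alignment, so
    ``n_mismatches + n_indels`` equals the edit distance between the two
    sequences and ``read_length`` is the number of alignment columns.
    """
    if not consensus or not reference:
        raise ValueError("read_accuracy requires non-empty sequences")
    aln = global_align(consensus, reference, EDIT_SCORING)
    length = aln.n_columns
    indels = aln.insertions + aln.deletions
    accuracy = (length - (aln.mismatches + indels)) / length * 100.0
    return AccuracyResult(length, aln.mismatches, indels, accuracy)


def assign_reference(
    consensus: str,
    references: Sequence[SequenceRecord],
    min_identity: float = DEFAULT_ASSIGN_IDENTITY,
) -> str | None:
    """Best-identity reference for a consensus, or None below the floor.

    Both orientations are tried; ties keep the first reference in input
    order (and the forward orientation), deterministically.
    """
    best_id = None
    best_identity = -1.0
    rc = reverse_complement(consensus)
    for ref in references:
        for seq in (consensus, rc):
            identity = global_align(seq, ref.sequence).identity
            if identity > best_identity:
                best_identity = identity
                best_id = ref.id
    if best_identity >= min_identity:
        return best_id
    return None


def quantify(
    records: Sequence[ConsensusRecord],
    references: Sequence[SequenceRecord],
    min_identity: float = DEFAULT_ASSIGN_IDENTITY,
) -> dict[str, int]:
    """Consensus counts per reference under the strand policy.

    Only PASS records of class reverse or hairpin are counted; forward and
    unclassified records are excluded.  Children of split fused reads count
    independently.
    """
    if not references:
        raise ValueError("quantify requires at least one reference")
    counts = {ref.id: 0 for ref in references}
    for rec in records:
        if rec.status != "pass" or rec.read_class not in ("reverse", "hairpin"):
            continue
        ref_id = assign_reference(rec.consensus, references, min_identity)
        if ref_id is not None:
            counts[ref_id] += 1
    return counts


def recovery_fit(
    counts: Mapping[str, int],
    input_proportions: Mapping[str, float],
    scale: str = "log",
    pseudocount: float = 0.5,
) -> float:
    """R^2 of recovered counts against input proportions.

    The default log10 fit spans mixes covering orders of magnitude (a
    1:10:100 spike-in); a linear-scale fit would be dominated by the
    largest class.  ``counts`` gets a pseudocount so zero classes stay
    finite on the log scale.
    """
    keys = list(input_proportions)
    if len(keys) < 3:
        raise ValueError("recovery_fit needs at least three references")
    missing = [k for k in keys if k not in counts]
    if missing:
        raise ValueError(f"counts missing references: {missing}")
    props = np.array([input_proportions[k] for k in keys], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("input proportions must sum to 1")
    y = np.array([counts[k] for k in keys], dtype=float)
    if scale == "log":
        x = np.log10(props)
        y = np.log10(y + pseudocount)
    elif scale == "linear":
        x = props
    else:
        raise ValueError(f"unknown fit scale {scale!r}")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in input proportions")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
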