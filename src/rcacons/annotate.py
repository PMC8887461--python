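"""Adaptor scanning, read-artifact classification and fused-read splitting.

A rolling-circle concatemeric read carries many copies of the ligation
adaptor, each flanking one insert.  This module locates every adaptor copy
(on either strand), looks for leftover sequencing-adaptor remnants, and
classifies each read:

``forward``
    all adaptor copies in the orientation of the adaptor as given
    (second-strand cDNA; typically fragmented, excluded from counting),
``reverse``
    all copies reverse-complemented (first-strand cDNA),
``fused``
    two molecules reported as one read; betrayed by an internal
    sequencing-adaptor remnant (with or without a strand flip).  Fused
    reads are split at each internal remnant, excising the remnant span,
``hairpin``
    a strand flip with no remnant at the junction: the cDNA self-primed
    and the read continues into its own reverse complement.  Hairpin reads
    are deliberately left whole — the mirrored half doubles the usable
    insert copies,
``unclassified``
    fewer than two adaptor copies found.

Adaptor hits are extracted greedily: the best semiglobal hit (either
strand) above the identity floor is taken, then the flanking segments are
scanned recursively, which guarantees non-overlapping, deterministic hits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import Alignment, Scoring, DEFAULT_SCORING, reverse_complement, semiglobal_align
from .core_io import Adaptor, FilterConfig, SequenceRecord

#: Remnant hits within this many nt of a read end are trimming leftovers,
#: never fusion evidence.
TERMINAL_MARGIN = 5

READ_CLASSES = ("forward", "reverse", "fused", "hairpin", "unclassified")


@dataclass(frozen=True)
class AdaptorHit:
    """One located adaptor copy on a read (0-based half-open coordinates)."""

    adaptor_name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    identity: float
    score: int


@dataclass
class ReadAnnotation:
    """Per-read hit list, remnant hits, artifact class and split points."""

    read_id: str
    hits: list[AdaptorHit] = field(default_factory=list)
    remnant_hits: list[AdaptorHit] = field(default_factory=list)
    read_class: str = "unclassified"
    split_points: list[int] = field(default_factory=list)


def _best_hit(
    segment: str,
    adaptors: Sequence[Adaptor],
    scoring: Scoring,
) -> Optional[tuple[Alignment, str, str]]:
    """Best (alignment, strand, adaptor_name) over all adaptors and strands."""
    best: Optional[tuple[Alignment, str, str]] = None
    for adaptor in adaptors:
        for strand, query in (("+", adaptor.sequence), ("-", reverse_complement(adaptor.sequence))):
            aln = semiglobal_align(query, segment, scoring)
            if best is None or aln.score > best[0].score:
                best = (aln, strand, adaptor.name)
    return best


def _scan_segment(
    seq: str,
    adaptors: Sequence[Adaptor],
    lo: int,
    hi: int,
    min_identity: float,
    min_seg: int,
    scoring: Scoring,
    out: list[AdaptorHit],
) -> None:
    if hi - lo < min_seg:
        return
    found = _best_hit(seq[lo:hi], adaptors, scoring)
    if found is None:
        return
    aln, strand, name = found
    if aln.identity < min_identity or aln.end <= aln.start:
        return
    out.append(
        AdaptorHit(name, lo + aln.start, lo + aln.end, strand, aln.identity, aln.score)
    )
    _scan_segment(seq, adaptors, lo, lo + aln.start, min_identity, min_seg, scoring, out)
    _scan_segment(seq, adaptors, lo + aln.end, hi, min_identity, min_seg, scoring, out)


def scan_adaptors(
    read: SequenceRecord,
    adaptors: Sequence[Adaptor],
    config: FilterConfig,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[AdaptorHit]:
    """All non-overlapping adaptor copies on a read, sorted by start.

    Greedy mask-and-rescan: take the best hit above
    ``config.adaptor_identity_min``, then scan the two flanks recursively.
    Returns an empty list when the read is shorter than every adaptor.
    """
    if not adaptors:
        return []
    min_len = min(a.length for a in adaptors)
    if len(read.sequence) < min_len:
        return []
    # a hit needs at least identity*length matching columns, so shorter
    # segments cannot host an acceptable hit
    min_seg = max(1, math.ceil(min_len * config.adaptor_identity_min))
    hits: list[AdaptorHit] = []
    _scan_segment(
        read.sequence, adaptors, 0, len(read.sequence),
        config.adaptor_identity_min, min_seg, scoring, hits,
    )
    hits.sort(key=lambda h: h.start)
    return hits


def scan_adaptor(
    read: SequenceRecord,
    adaptor: Adaptor,
    config: FilterConfig,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[AdaptorHit]:
    """Single-adaptor convenience wrapper around :func:`scan_adaptors`."""
    return scan_adaptors(read, [adaptor], config, scoring)


def detect_remnants(
    read: SequenceRecord,
    sequencing_adaptors: Sequence[Adaptor],
    min_identity: float = 0.70,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[AdaptorHit]:
    """Locate leftover sequencing-adaptor copies (e.g. ONT adapters).

    Same greedy non-overlap contract as :func:`scan_adaptors`.  An empty
    adaptor set disables the feature and returns [].
    """
    if not sequencing_adaptors:
        return []
    min_len = min(a.length for a in sequencing_adaptors)
    if len(read.sequence) < min_len:
        return []
    min_seg = max(1, math.ceil(min_len * min_identity))
    hits: list[AdaptorHit] = []
    _scan_segment(
        read.sequence, sequencing_adaptors, 0, len(read.sequence),
        min_identity, min_seg, scoring, hits,
    )
    hits.sort(key=lambda h: h.start)
    return hits


def _internal_remnants(remnant_hits: Sequence[AdaptorHit], read_len: int) -> list[AdaptorHit]:
    return [
        h
        for h in remnant_hits
        if h.start >= TERMINAL_MARGIN and h.end <= read_len - TERMINAL_MARGIN
    ]


def classify_read(
    hits: Sequence[AdaptorHit],
    remnant_hits: Sequence[AdaptorHit],
    read: SequenceRecord,
) -> ReadAnnotation:
    """Assign the artifact class from hit strands and internal remnants.

    Rules: fewer than two hits -> unclassified; any internal (non-terminal)
    sequencing-adaptor remnant -> fused, split at each remnant midpoint;
    a strand flip without remnant -> hairpin (self-priming leaves no
    sequencing adaptor at the junction); otherwise forward or reverse by
    the shared hit orientation.
    """
    ann = ReadAnnotation(read_id=read.id, hits=list(hits), remnant_hits=list(remnant_hits))
    if len(hits) < 2:
        ann.read_class = "unclassified"
        return ann
    internal = _internal_remnants(remnant_hits, len(read.sequence))
    strands = {h.strand for h in hits}
    if internal:
        ann.read_class = "fused"
        ann.split_points = sorted((h.start + h.end) // 2 for h in internal)
        return ann
    if len(strands) > 1:
        ann.read_class = "hairpin"
        return ann
    ann.read_class = "forward" if strands == {"+"} else "reverse"
    return ann


def annotate_read(
    read: SequenceRecord,
    adaptors: Sequence[Adaptor],
    remnant_adaptors: Sequence[Adaptor],
    config: FilterConfig,
    scoring: Scoring = DEFAULT_SCORING,
) -> ReadAnnotation:
    """scan + remnant detection + classification in one call."""
    remnant_hits = detect_remnants(read, remnant_adaptors, config.adaptor_identity_min, scoring)
    hits = scan_adaptors(read, adaptors, config, scoring)
    return classify_read(hits, remnant_hits, read)


def split_fused(read: SequenceRecord, annotation: ReadAnnotation) -> list[SequenceRecord]:
    """Split a fused read at each internal remnant, excising the remnant.

    Children are named ``<read_id>/1``, ``<read_id>/2``, ... in read order;
    concatenating the children plus the excised remnant spans reconstructs
    the parent.  Non-fused reads (including hairpins, which are kept whole
    by design) are returned unchanged as singletons.
    """
    if annotation.read_class != "fused":
        return [read]
    n = len(read.sequence)
    spans = []
    internal = _internal_remnants(annotation.remnant_hits, n)
    for sp in annotation.split_points:
        if not 0 <= sp < n:
            raise RuntimeError(f"split point {sp} outside read {read.id!r} (length {n})")
        owner = [h for h in internal if (h.start + h.end) // 2 == sp]
        if not owner:
            raise RuntimeError(f"no remnant hit owns split point {sp} on read {read.id!r}")
        spans.append((owner[0].start, owner[0].end))
    spans.sort()
    children: list[SequenceRecord] = []
    cursor = 0
    pieces = []
    for s, e in spans:
        pieces.append((cursor, s))
        cursor = e
    pieces.append((cursor, n))
    idx = 0
    for s, e in pieces:
        if e <= s:
            continue
        idx += 1
        qual = read.quality[s:e] if read.quality is not None else None
        children.append(SequenceRecord(f"{read.id}/{idx}", read.sequence[s:e], qual))
    return children
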