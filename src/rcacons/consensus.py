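"""Insert extraction, multiple alignment and per-read consensus calling.

Every gap between two adjacent adaptor copies is a candidate insert; the
copies of one read are aligned together and their plurality consensus
corrects the nanopore errors.  The workflow mirrors the two-pass scheme of
concatemer consensus callers: align all inserts, drop rows whose mean
pairwise identity is below a floor (chimeric or badly basecalled copies),
re-align the survivors from scratch, then call the consensus.

The MSA is an in-house progressive aligner: inserts are <=40 nt and a read
rarely holds more than ~25 copies, so exact pairwise DP plus profile
merging is fast, dependency-free and deterministic (guide order is by
score to the medoid insert, ties by input index).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _dp
from .align import global_align, reverse_complement
from .annotate import ReadAnnotation
from .core_io import FilterConfig, SequenceRecord

_SYMBOLS = "ACGTN-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP = _SYM_INDEX["-"]
_N = _SYM_INDEX["N"]

# mean per-row score of a profile column against an incoming base:
# match +1, mismatch -1, N matches nothing, a gap in a row scores like a gap
_COLUMN_SCORES = np.full((6, 5), -1.0)
for _i in range(4):
    _COLUMN_SCORES[_i, _i] = 1.0
# N rows and N bases mismatch everything (including each other); gap rows
# score -1 against any base, same as the DP gap penalty
_GAP_PENALTY = -1.0


class TooFewInsertsError(ValueError):
    """Fewer than two inserts: no MSA, the read must be discarded."""


class LowQualityInsertsError(ValueError):
    """Fewer than two inserts survive the identity filter."""


@dataclass(frozen=True)
class Insert:
    """One extracted insert, canonicalised to reference-sense orientation."""

    read_id: str
    start: int
    end: int
    sequence: str
    source_strand: str


@dataclass
class MSAlignment:
    """Gapped rows over {A,C,G,T,N,-}; ``row_ids[r]`` is the insert index."""

    rows: list[str]
    row_ids: list[int]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array(
            [[_SYM_INDEX[c] for c in row] for row in self.rows], dtype=np.int8
        )


def extract_inserts(
    read: SequenceRecord,
    annotation: ReadAnnotation,
    config: FilterConfig,
) -> list[Insert]:
    """Inter-adaptor gaps within the configured length window.

    One candidate per gap between consecutive hits sharing a strand, plus
    the terminal gaps flanked by the read ends; candidates outside
    [insert_len_min, insert_len_max] are dropped (truncated terminal copies
    mostly fall out here).  Minus-strand inserts are reverse-complemented
    so all retained inserts are in canonical orientation.
    """
    hits = annotation.hits
    if len(hits) < 1:
        return []
    gaps: list[tuple[int, int, str]] = []
    if hits[0].start > 0:
        gaps.append((0, hits[0].start, hits[0].strand))
    for left, right in zip(hits, hits[1:]):
        if left.strand != right.strand:
            continue  # the hairpin junction gap is not a clean insert
        gaps.append((left.end, right.start, left.strand))
    if hits[-1].end < len(read.sequence):
        gaps.append((hits[-1].end, len(read.sequence), hits[-1].strand))
    inserts: list[Insert] = []
    for start, end, strand in gaps:
        length = end - start
        if not (config.insert_len_min <= length <= config.insert_len_max):
            continue
        seq = read.sequence[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        inserts.append(Insert(read.id, start, end, seq, strand))
    return inserts


def _merge(rows: list[str], seq: str) -> list[str]:
    """Align one sequence against the running profile; returns new rows."""
    k = len(rows)
    prof = np.array([[_SYM_INDEX[c] for c in row] for row in rows], dtype=np.int64)
    counts = np.zeros((prof.shape[1], 6), dtype=np.float64)
    for s in range(6):
        counts[:, s] = (prof == s).sum(axis=0)
    col_scores = counts @ _COLUMN_SCORES / k  # (P, 5)
    seq_codes = np.array([_SYM_INDEX[c] for c in seq], dtype=np.int64)
    sub = np.ascontiguousarray(col_scores[:, seq_codes])
    H = _dp.profile_fill(sub, _GAP_PENALTY)
    ops = _dp.profile_traceback(H, sub, _GAP_PENALTY)
    new_rows = [[] for _ in range(k + 1)]
    pi = si = 0
    for op in ops:
        if op == 0:  # aligned column
            for r in range(k):
                new_rows[r].append(rows[r][pi])
            new_rows[k].append(seq[si])
            pi += 1
            si += 1
        elif op == 1:  # profile column vs gap in new sequence
            for r in range(k):
                new_rows[r].append(rows[r][pi])
            new_rows[k].append("-")
            pi += 1
        else:  # new gap column vs sequence base
            for r in range(k):
                new_rows[r].append("-")
            new_rows[k].append(seq[si])
            si += 1
    return ["".join(r) for r in new_rows]


def align_sequences(seqs: Sequence[str], ids: Sequence[int] | None = None) -> MSAlignment:
    """Progressive MSA of short sequences.

    Guide order: the medoid (highest total pairwise score, ties by lowest
    index) seeds the profile; remaining sequences join by decreasing score
    to the medoid, ties by index.  Deterministic for a fixed input order.
    """
    k = len(seqs)
    if k < 2:
        raise TooFewInsertsError(f"need >=2 sequences for an MSA, got {k}")
    if ids is None:
        ids = list(range(k))
    scores = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            s = global_align(seqs[i], seqs[j]).score
            scores[i, j] = scores[j, i] = s
    medoid = int(np.argmax(scores.sum(axis=1)))  # first max -> lowest index
    order = sorted(
        (i for i in range(k) if i != medoid),
        key=lambda i: (-scores[medoid, i], i),
    )
    rows = [seqs[medoid]]
    row_ids = [ids[medoid]]
    for i in order:
        rows = _merge(rows, seqs[i])
        row_ids.append(ids[i])
    return MSAlignment(rows=rows, row_ids=row_ids)


def build_msa(inserts: Sequence[Insert]) -> MSAlignment:
    """MSA of all inserts extracted from one read."""
    return align_sequences([ins.sequence for ins in inserts])


def pairwise_identity_profile(msa: MSAlignment) -> np.ndarray:
    """Per-row mean pairwise identity.

    Identity of a pair = identical non-gap columns / columns where either
    row is non-gap (0 if the rows share no columns).  Returns the mean of
    each row against all others.
    """
    k = len(msa.rows)
    if k < 2:
        raise ValueError("identity profile needs at least two rows")
    m = msa.matrix()
    nongap = m != _GAP
    profile = np.zeros(k)
    for i in range(k):
        total = 0.0
        for j in range(k):
            if i == j:
                continue
            union = np.count_nonzero(nongap[i] | nongap[j])
            same = np.count_nonzero((m[i] == m[j]) & nongap[i] & nongap[j])
            total += same / union if union else 0.0
        profile[i] = total / (k - 1)
    return profile


def filter_inserts(
    msa: MSAlignment,
    profile: np.ndarray,
    config: FilterConfig,
) -> MSAlignment:
    """Drop rows below the identity floor and re-align the survivors.

    Raises :class:`LowQualityInsertsError` when fewer than two rows
    survive (the read is discarded with reason ``low_quality_inserts``).
    """
    keep = [r for r in range(len(msa.rows)) if profile[r] >= config.insert_identity_min]
    if len(keep) < 2:
        raise LowQualityInsertsError(
            f"only {len(keep)} inserts at identity >= {config.insert_identity_min}"
        )
    # preserve original insert order for the second-pass alignment
    keep.sort(key=lambda r: msa.row_ids[r])
    seqs = [msa.rows[r].replace("-", "") for r in keep]
    return align_sequences(seqs, [msa.row_ids[r] for r in keep])


def call_consensus(msa: MSAlignment) -> str:
    """Column-plurality consensus.

    Per column: the most frequent symbol wins; a strict gap plurality
    omits the column; base ties break in the fixed order A<C<G<T; N counts
    toward coverage but never beats a concrete base.
    """
    m = msa.matrix()
    counts = np.zeros((6, m.shape[1]), dtype=np.int64)
    for s in range(6):
        counts[s] = (m == s).sum(axis=0)
    out = []
    for col in range(m.shape[1]):
        c = counts[:, col]
        best_base = int(np.argmax(c[:4]))  # ties -> A<C<G<T by argmax order
        top = c[best_base]
        if c[_GAP] > max(top, c[_N]):
            continue
        if c[_N] > top:
            out.append("N")
        elif top > 0:
            out.append(_SYMBOLS[best_base])
        elif c[_N] > 0:
            out.append("N")
        # all-gap column (cannot happen in a well-formed MSA): omitted
    return "".join(out)
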