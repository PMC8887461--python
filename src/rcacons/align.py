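"""Deterministic pairwise alignment engine.

Two flavours are exposed:

``semiglobal_align``
    The full query is aligned against any substring of the target (free
    end-gaps on the target only).  This is the primitive behind adaptor
    scanning: a short adaptor oligo is searched inside a long noisy read.

``global_align``
    End-to-end alignment of two sequences, used for insert comparison,
    reference assignment and the read-accuracy metric.

Scoring is unit match/mismatch/linear-gap (+1/-1/-1 by default); the
adaptors involved are 20-30 nt, where affine gap models buy nothing and a
unit scheme keeps the engine trivially oracle-checkable.  ``N`` matches
nothing (scores as a mismatch), a conservative treatment of basecaller
ambiguity codes.

Determinism: the reported alignment is the one with the smallest end
coordinate among maximal-scoring ends, traced back with a fixed move
preference (diagonal, then deletion, then insertion), so repeated runs are
byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dp

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch/linear-gap integer scores."""

    match: int = 1
    mismatch: int = -1
    gap: int = -1


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class Alignment:
    """One pairwise alignment.

    ``start``/``end`` are 0-based half-open coordinates on the target.
    ``insertions`` count target bases opposite a gap in the query;
    ``deletions`` count query bases opposite a gap in the target, so
    ``matches + mismatches + deletions`` equals the query length consumed.
    """

    score: int
    start: int
    end: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int

    @property
    def n_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        n = self.n_columns
        return self.matches / n if n else 0.0


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"cannot reverse-complement characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str, name: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"{name} contains invalid characters {bad}")
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def semiglobal_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Best alignment of the full ``query`` to any substring of ``target``.

    End-gaps on the target are free; the query is always fully consumed.
    ``start`` may equal ``end`` in the degenerate case where the optimum
    aligns every query base to a gap (identity 0).
    """
    q = _encode(query, "query")
    t = _encode(target, "target")
    H = _dp.fill_matrix(q, t, scoring.match, scoring.mismatch, scoring.gap, True)
    last = H[q.shape[0]]
    j_end = int(np.argmax(last))  # first occurrence -> smallest end
    start, ma, mm, ins, de = _dp.traceback(
        H, q, t, scoring.match, scoring.mismatch, scoring.gap, j_end
    )
    return Alignment(int(last[j_end]), int(start), j_end, int(ma), int(mm), int(ins), int(de))


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """End-to-end alignment of ``a`` (query) against ``b`` (target).

    Among co-optimal alignments the one maximising the number of matched
    columns is reported.  That canonicalisation determines the whole count
    vector algebraically (given the score, lengths and match count) and is
    symmetric in the two sequences, so ``global_align(a, b)`` and
    ``global_align(b, a)`` have equal score with insertions and deletions
    swapped.  Falls back to a traceback when ``mismatch == 2 * gap`` makes
    a mismatch indistinguishable from an insertion-deletion pair.
    """
    q = _encode(a, "a")
    t = _encode(b, "b")
    denom = scoring.mismatch - 2 * scoring.gap
    if denom != 0:
        H, M = _dp.fill_matrix_matches(q, t, scoring.match, scoring.mismatch, scoring.gap)
        score = int(H[-1, -1])
        ma = int(M[-1, -1])
        # score = match*ma + mismatch*mm + gap*(|a| + |b| - 2ma - 2mm)
        mm = (score - scoring.match * ma - scoring.gap * (len(a) + len(b) - 2 * ma)) // denom
        de = len(a) - ma - mm
        ins = len(b) - ma - mm
        return Alignment(score, 0, len(b), ma, mm, ins, de)
    H = _dp.fill_matrix(q, t, scoring.match, scoring.mismatch, scoring.gap, False)
    leftover, ma, mm, ins, de = _dp.traceback(
        H, q, t, scoring.match, scoring.mismatch, scoring.gap, t.shape[0]
    )
    # target columns left of the traced path are leading insertions
    return Alignment(
        int(H[-1, -1]), 0, len(b), int(ma), int(mm), int(ins) + int(leftover), int(de)
    )
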