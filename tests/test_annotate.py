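"""Adaptor scanning, artifact classification and fused-read splitting."""
import edlib
import numpy as np
import pytest

from rcacons import (
    DEFAULT_ADAPTOR,
    DEFAULT_REMNANT,
    ErrorModel,
    FilterConfig,
    SequenceRecord,
    SimParams,
    AdaptorHit,
    classify_read,
    detect_remnants,
    make_clean_concatemer,
    random_insert,
    reverse_complement,
    scan_adaptor,
    scan_adaptors,
    simulate_reads,
    split_fused,
)
from rcacons.annotate import annotate_read

ADR = DEFAULT_ADAPTOR
REMNANT = DEFAULT_REMNANT


def _concatemer_read(rng, n_repeats=5, insert_len=30, rc=False):
    insert = random_insert(insert_len, rng, "ins")
    seq = make_clean_concatemer(insert.sequence, ADR.sequence, n_repeats)
    if rc:
        seq = reverse_complement(seq)
    return SequenceRecord("read", seq), insert


class TestScanAdaptors:
    def test_error_free_concatemer_hits_at_unit_starts(self, rng, filters):
        read, _ = _concatemer_read(rng, n_repeats=5)
        hits = scan_adaptor(read, ADR, filters)
        assert [h.start for h in hits] == [0, 54, 108, 162, 216]
        assert all(h.strand == "+" for h in hits)
        assert all(h.identity == 1.0 for h in hits)

    def test_read_shorter_than_adaptor_returns_empty(self, filters):
        assert scan_adaptor(SequenceRecord("r", "ACGTACGTAC"), ADR, filters) == []

    def test_reverse_complement_read_hits_minus_strand(self, rng, filters):
        read, _ = _concatemer_read(rng, n_repeats=4, rc=True)
        hits = scan_adaptor(read, ADR, filters)
        assert len(hits) == 4
        assert all(h.strand == "-" for h in hits)

    def test_hits_are_sorted_and_non_overlapping(self, rng, filters):
        params = SimParams(
            inserts=[(random_insert(30, rng, "x"), 1.0)], n_reads=20, seed=4
        )
        reads, _ = simulate_reads(params)
        for read in reads:
            hits = scan_adaptor(read, ADR, filters)
            for a, b in zip(hits, hits[1:]):
                assert a.end <= b.start

    def test_copy_recovery_matches_edlib_greedy_oracle(self, filters):
        """Mean copies recovered on noisy 8-repeat reads within one copy of
        an independent greedy edlib-based scan of the same reads."""
        rng = np.random.default_rng(31)
        insert = random_insert(30, rng, "x")
        unit = len(ADR.sequence) + 30
        params = SimParams(
            inserts=[(insert, 1.0)],
            n_reads=50,
            seed=8,
            read_len_mean=8 * unit,
            read_len_sd=0.0,
            class_fractions={"forward": 0.0, "reverse": 1.0, "fused": 0.0, "hairpin": 0.0},
        )
        reads, _ = simulate_reads(params)
        max_dist = int((1 - filters.adaptor_identity_min) * ADR.length)
        ours, oracle = [], []
        for read in reads:
            ours.append(len(scan_adaptor(read, ADR, filters)))
            oracle.append(_edlib_greedy_count(read.sequence, ADR.sequence, max_dist))
        assert abs(np.mean(ours) - np.mean(oracle)) <= 1.0


def _edlib_greedy_count(seq, adaptor, max_dist):
    queries = [adaptor, reverse_complement(adaptor)]
    count = 0
    work = seq
    while True:
        best = None
        for q in queries:
            res = edlib.align(q, work, mode="HW", task="locations", k=max_dist)
            if res["editDistance"] == -1:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], res["locations"][0])
        if best is None:
            return count
        count += 1
        s, e = best[1]
        work = work[:s] + "#" * (e + 1 - s) + work[e + 1:]


class TestDetectRemnants:
    def test_embedded_sequencing_adaptor_found(self, rng):
        flank = random_insert(100, rng, "f").sequence
        read = SequenceRecord("r", flank + REMNANT.sequence + flank)
        hits = detect_remnants(read, [REMNANT])
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (100, 100 + REMNANT.length)

    def test_empty_remnant_set_disables_feature(self, rng):
        read = SequenceRecord("r", random_insert(200, rng, "f").sequence)
        assert detect_remnants(read, []) == []


class TestClassifyRead:
    def _hit(self, start, strand, name="ADR24"):
        return AdaptorHit(name, start, start + 24, strand, 1.0, 24)

    def test_all_minus_hits_is_reverse(self):
        read = SequenceRecord("r", "A" * 300)
        hits = [self._hit(54 * i, "-") for i in range(5)]
        ann = classify_read(hits, [], read)
        assert ann.read_class == "reverse"

    def test_all_plus_hits_is_forward(self):
        read = SequenceRecord("r", "A" * 300)
        hits = [self._hit(54 * i, "+") for i in range(5)]
        assert classify_read(hits, [], read).read_class == "forward"

    def test_strand_flip_with_internal_remnant_is_fused(self):
        read = SequenceRecord("r", "A" * 400)
        hits = [self._hit(54 * i, "+") for i in range(3)] + [
            self._hit(220 + 54 * i, "-") for i in range(3)
        ]
        remnant = AdaptorHit("SEQADPT", 180, 210, "+", 1.0, 30)
        ann = classify_read(hits, [remnant], read)
        assert ann.read_class == "fused"
        assert ann.split_points == [195]

    def test_strand_flip_without_remnant_is_hairpin(self):
        read = SequenceRecord("r", "A" * 500)
        hits = [self._hit(54 * i, "-") for i in range(4)] + [
            self._hit(240 + 54 * i, "+") for i in range(4)
        ]
        ann = classify_read(hits, [], read)
        assert ann.read_class == "hairpin"
        assert ann.split_points == []

    def test_terminal_remnant_is_not_fusion_evidence(self):
        read = SequenceRecord("r", "A" * 300)
        hits = [self._hit(40 + 54 * i, "+") for i in range(4)]
        terminal = AdaptorHit("SEQADPT", 0, 30, "+", 1.0, 30)
        assert classify_read(hits, [terminal], read).read_class == "forward"

    def test_fewer_than_two_hits_unclassified(self):
        read = SequenceRecord("r", "A" * 100)
        assert classify_read([self._hit(0, "+")], [], read).read_class == "unclassified"


class TestSplitFused:
    def test_children_exclude_remnant_and_conserve_bases(self, rng, filters):
        left = random_insert(290, rng, "l").sequence
        right = random_insert(290, rng, "r").sequence
        remnant_seq = REMNANT.sequence[:20]
        read = SequenceRecord("fr", left + remnant_seq + right)
        hit = AdaptorHit("SEQADPT", 290, 310, "+", 1.0, 20)
        ann = classify_read(
            [AdaptorHit("A", 0, 24, "+", 1.0, 24), AdaptorHit("A", 320, 344, "-", 1.0, 24)],
            [hit],
            read,
        )
        children = split_fused(read, ann)
        assert [len(c.sequence) for c in children] == [290, 290]
        assert [c.id for c in children] == ["fr/1", "fr/2"]
        assert children[0].sequence + remnant_seq + children[1].sequence == read.sequence

    def test_non_fused_read_returned_unchanged(self, rng, filters):
        read, _ = _concatemer_read(rng, n_repeats=4)
        ann = annotate_read(read, [ADR], [REMNANT], filters)
        assert ann.read_class == "forward"
        (same,) = split_fused(read, ann)
        assert same is read

    def test_hairpin_read_left_untouched(self, filters):
        rng = np.random.default_rng(77)
        insert = random_insert(30, rng, "x")
        half = make_clean_concatemer(insert.sequence, ADR.sequence, 4)
        read = SequenceRecord("hp", reverse_complement(half) + half)
        ann = annotate_read(read, [ADR], [REMNANT], filters)
        assert ann.read_class == "hairpin"
        (same,) = split_fused(read, ann)
        assert same.sequence == read.sequence

    def test_base_conservation_on_simulated_fused_reads(self, filters):
        rng = np.random.default_rng(13)
        params = SimParams(
            inserts=[(random_insert(30, rng, "x"), 1.0)],
            n_reads=25,
            seed=5,
            class_fractions={"forward": 0.0, "reverse": 0.0, "fused": 1.0, "hairpin": 0.0},
        )
        reads, _ = simulate_reads(params)
        for read in reads:
            ann = annotate_read(read, [ADR], [REMNANT], filters)
            if ann.read_class != "fused":
                continue
            children = split_fused(read, ann)
            excised = sum(
                h.end - h.start
                for h in ann.remnant_hits
                if (h.start + h.end) // 2 in ann.split_points
            )
            assert sum(len(c.sequence) for c in children) + excised == len(read.sequence)


class TestOrientationInvolution:
    def test_scan_classify_mirror_on_error_free_reads(self, filters):
        """Reverse-complementing a read mirrors the classification
        (forward<->reverse) and reflects hit coordinates."""
        params = SimParams(
            inserts=[(random_insert(30, np.random.default_rng(3), "x"), 1.0)],
            n_reads=30,
            seed=17,
            error_model=ErrorModel(0.0, 0.0, 0.0),
        )
        reads, truths = simulate_reads(params)
        mirror = {"forward": "reverse", "reverse": "forward",
                  "hairpin": "hairpin", "fused": "fused", "unclassified": "unclassified"}
        for read in reads:
            ann = annotate_read(read, [ADR], [REMNANT], filters)
            flipped = SequenceRecord(read.id, reverse_complement(read.sequence))
            ann_rc = annotate_read(flipped, [ADR], [REMNANT], filters)
            assert ann_rc.read_class == mirror[ann.read_class]
            n = len(read.sequence)
            starts = sorted(n - h.end for h in ann.hits)
            assert [h.start for h in ann_rc.hits] == starts
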