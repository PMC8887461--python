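"""Run the full concatemer-to-consensus pipeline on a simulated library.

Every read is scanned for adaptor copies, classified (fused reads are
split, hairpin reads kept whole), its inserts are extracted and aligned,
and a plurality consensus is called; the QC filters then decide pass or
discard with a single reason tag.
"""
from collections import Counter

import numpy as np

from rcacons import (
    DEFAULT_ADAPTOR,
    DEFAULT_REMNANT,
    FilterConfig,
    SimParams,
    process_library,
    random_insert,
    read_accuracy,
    simulate_reads,
)

rng = np.random.default_rng(1)
insert = random_insert(30, rng, "ins")
params = SimParams(inserts=[(insert, 1.0)], n_reads=200, seed=7)
reads, truths = simulate_reads(params)

records = process_library(reads, [DEFAULT_ADAPTOR], [DEFAULT_REMNANT], FilterConfig())

print(f"input reads: {len(reads)}; read units after splitting: {len(records)}")
print("class counts:", dict(Counter(r.read_class for r in records)))
print("status:", dict(Counter(r.status for r in records)))
print("discard reasons:", dict(Counter(r.discard_reason for r in records if r.status != "pass")))

accs = [read_accuracy(r.consensus, insert.sequence).accuracy_pct
        for r in records if r.status == "pass"]
print(f"median consensus accuracy vs true insert: {np.median(accs):.1f}%")
# At 10% raw per-base error the repeat redundancy corrects almost every
# position: the consensus is typically a perfect copy of the 30-nt insert.
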