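"""Independent brute-force oracles used by the test suite only.

Pure-Python dynamic programming (no numpy/numba) plus edlib as a second,
third-party route.  These must never share code with the package.
"""
from __future__ import annotations


def semiglobal_score_bruteforce(q: str, t: str, match=1, mismatch=-1, gap=-1) -> int:
    """Best score of the full query vs any substring of the target."""
    n = len(t)
    prev = [0] * (n + 1)
    for i in range(1, len(q) + 1):
        cur = [prev[0] + gap] + [0] * n
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if (qi == t[j - 1] and qi != "N") else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(prev)


def global_score_bruteforce(a: str, b: str, match=1, mismatch=-1, gap=-1) -> int:
    """End-to-end alignment score."""
    n = len(b)
    prev = [gap * j for j in range(n + 1)]
    for i in range(1, len(a) + 1):
        cur = [gap * i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[n]


def levenshtein(a: str, b: str) -> int:
    """Classic unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i in range(1, len(a) + 1):
        cur = [i] + [0] * len(b)
        for j in range(1, len(b) + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[len(b)]


def identity_profile_bruteforce(rows: list[str]) -> list[float]:
    """Per-row mean pairwise identity, recomputed with plain string loops."""
    k = len(rows)
    out = []
    for i in range(k):
        total = 0.0
        for j in range(k):
            if i == j:
                continue
            same = union = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                union += 1
                if a == b:
                    same += 1
            total += same / union if union else 0.0
        out.append(total / (k - 1))
    return out


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(length))
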