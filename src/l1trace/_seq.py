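"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNYacgtny", "TGCANRtgcanr")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def trailing_run(seq: str, base: str = "A") -> int:
    """Length of the maximal run of `base` ending at the 3' end of seq."""
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def leading_run(seq: str, base: str = "A") -> int:
    n = 0
    for ch in seq:
        if ch != base:
            break
        n += 1
    return n


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def shared_kmer_count(a: str, b: str, k: int = 15) -> int:
    """Number of k-mers of `a` that occur in `b` (set semantics)."""
    if len(a) < k or len(b) < k:
        return 0
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return sum(1 for i in range(len(a) - k + 1) if a[i : i + k] in kb)
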