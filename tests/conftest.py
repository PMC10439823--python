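"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by direct enumeration (all
windows, all chains, per-base boolean arrays) so they stay independent of
the vectorised/DP code paths they check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from minite import TEAnnotation, encode_kmer, hash_code

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_minimizers(seq: str, k: int, w: int):
    """All-windows minimum enumeration of canonical winnowed minimizers.

    Returns a set of (code, pos, strand) triples: for every window of w
    bases, every valid k-mer attaining the window's minimum canonical hash.
    """
    n = len(seq) - k + 1
    assert n >= 1
    hashes: list[int | None] = []
    strands: list[str] = []
    for p in range(n):
        kmer = seq[p:p + k].upper()
        fwd = encode_kmer(kmer)
        if fwd is None:
            hashes.append(None)
            strands.append("+")
            continue
        rc = encode_kmer(revcomp(kmer))
        hf, hr = hash_code(fwd, k), hash_code(rc, k)
        if hf <= hr:
            hashes.append(hf)
            strands.append("+")
        else:
            hashes.append(hr)
            strands.append("-")
    wk = min(w - k + 1, n)
    out = set()
    for start in range(n - wk + 1):
        window = [(hashes[p], p) for p in range(start, start + wk)
                  if hashes[p] is not None]
        if not window:
            continue
        m = min(h for h, _ in window)
        for h, p in window:
            if h == m:
                out.add((h, p, strands[p]))
    return out


def chain_compatible(i, j, sign: int, max_gap: int, band: int) -> bool:
    """Chain-extension predicate: may hit j extend hit i?

    Hits are (subject, query) pairs; written independently of the DP code.
    """
    ds = j[0] - i[0]
    dq = sign * (j[1] - i[1])
    return ds > 0 and dq > 0 and ds <= max_gap and abs(ds - dq) <= band


def brute_force_best_chain_score(hits, sign: int, max_gap: int,
                                 band: int) -> int:
    """Exhaustive longest-colinear-chain score via memoised recursion."""
    hits = sorted(hits)

    @lru_cache(maxsize=None)
    def longest_from(i: int) -> int:
        best = 1
        for j in range(i + 1, len(hits)):
            if chain_compatible(hits[i], hits[j], sign, max_gap, band):
                best = max(best, 1 + longest_from(j))
        return best

    return max((longest_from(i) for i in range(len(hits))), default=0)


def coverage_array(annotations, seq_lengths: dict[str, int]):
    """Per-base boolean coverage oracle: dict seq_name -> bool array."""
    cov = {name: np.zeros(L, dtype=bool) for name, L in seq_lengths.items()}
    for a in annotations:
        cov[a.seq_name][a.first - 1:a.last] = True
    return cov


def random_annotations(rng, n: int, seq_names, max_pos: int = 5_000,
                       max_len: int = 400):
    """Random interval sets for oracle-equivalence tests."""
    out = []
    for _ in range(n):
        name = seq_names[rng.integers(len(seq_names))]
        first = int(rng.integers(1, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(TEAnnotation(name, first, first + length - 1,
                                family=f"F{int(rng.integers(3))}"))
    return out


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of
    # execution order
    return np.random.default_rng(20230511)
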