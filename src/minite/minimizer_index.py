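"""Genome minimizer index.

The genome is indexed by winnowing: every k-mer is hashed with an invertible
mixing function, and within each window of ``w`` consecutive bases the
k-mer(s) with the minimum hash are kept.  Both strands fold onto one code by
canonicalisation: the stored code is the smaller of the forward-strand and
reverse-complement hashes, with the winning orientation recorded, so TE
copies on either strand remain discoverable.  Defaults are k = 15 and
w = 20, the standard seeding regime for mapping noisy long queries.

K-mers containing degenerate IUPAC codes (anything outside ACGT) cannot be
2-bit encoded and are excluded from minimizer candidacy; windows consisting
solely of such k-mers contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import GenomeAssembly

__all__ = [
    "IndexParams",
    "MinimizerOccurrence",
    "MinimizerIndex",
    "encode_kmer",
    "hash_code",
    "extract_minimizers",
    "build_index",
]

# 2-bit base encoding; every other byte maps to "invalid".
_BASE_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lowercase

_U64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class IndexParams:
    """Winnowing parameters: k-mer length and window length, in bp.

    ``max_code_occurrences`` optionally caps the occurrence list stored per
    minimizer code, guarding pathological low-complexity inputs; by default
    no per-code cap is applied (the only default cap is per-TE, at hit
    collection time).
    """

    k: int = 15
    w: int = 20
    max_code_occurrences: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 31):
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.w < self.k:
            raise ValueError(f"w ({self.w}) must be >= k ({self.k})")

    @property
    def mask(self) -> int:
        return (1 << (2 * self.k)) - 1


@dataclass(frozen=True)
class MinimizerOccurrence:
    """One genomic location of a minimizer code.

    ``strand`` is '+' when the forward-strand k-mer reading attained the
    canonical (minimum) hash, '-' when the reverse complement did.
    """

    seq_index: int
    pos: int
    strand: str


def encode_kmer(kmer: str) -> int | None:
    """2-bit encode a k-mer (A=0, C=1, G=2, T=3) into a 2k-bit integer.

    Returns ``None`` for k-mers containing any character outside ACGT/acgt
    (degenerate IUPAC codes cannot seed minimizers).
    """
    code = 0
    for ch in kmer:
        b = _BASE_CODES[ord(ch)]
        if b < 0:
            return None
        code = (code << 2) | int(b)
    return code


def hash_code(code: int, k: int) -> int:
    """Invertible multiply/xor-shift mixing hash on [0, 4**k).

    Bijective for every k in [1, 31]: each step is either a multiplication
    by an odd constant modulo 2**(2k) or an xor with a right shift, both of
    which are invertible.  Acts as the pseudo-random ordering that makes
    windowed-minimum selection an unbiased k-mer subsample.
    """
    mask = (1 << (2 * k)) - 1
    x = code & mask
    x = ((mask - x) + (x << 21)) & mask  # x *= (2**21 - 1), plus constant
    x ^= x >> 24
    x = (x + (x << 3) + (x << 8)) & mask  # x *= 265
    x ^= x >> 14
    x = (x + (x << 2) + (x << 4)) & mask  # x *= 21
    x ^= x >> 28
    x = (x + (x << 31)) & mask
    return x


def _hash_array(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised twin of :func:`hash_code` on a uint64 array."""
    mask = np.uint64((1 << (2 * k)) - 1)
    x = codes & mask
    x = ((mask - x) + (x << np.uint64(21))) & mask
    x ^= x >> np.uint64(24)
    x = (x + (x << np.uint64(3)) + (x << np.uint64(8))) & mask
    x ^= x >> np.uint64(14)
    x = (x + (x << np.uint64(2)) + (x << np.uint64(4))) & mask
    x ^= x >> np.uint64(28)
    x = (x + (x << np.uint64(31))) & mask
    return x


def _kmer_code_arrays(seq: str, k: int):
    """Forward codes, reverse-complement codes and validity for all k-mers.

    Returns ``(fwd, rc, valid)`` over the ``len(seq) - k + 1`` k-mer start
    positions; codes at invalid positions are meaningless.
    """
    b = _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    invalid = (b < 0).astype(np.int32)
    run = np.cumsum(invalid)
    bad_in_window = run[k - 1:] - np.concatenate(([0], run[:n - 1]))
    valid = bad_in_window == 0

    bu = np.where(b < 0, 0, b).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | bu[j:j + n]
    comp = np.uint64(3) - bu
    for j in range(k - 1, -1, -1):
        rc = (rc << np.uint64(2)) | comp[j:j + n]
    return fwd, rc, valid


def canonical_kmer_hashes(seq: str, k: int):
    """Canonical hash, orientation and validity for every k-mer of ``seq``.

    Returns ``(canon, fwd_wins, valid)``: ``canon[i]`` is
    ``min(hash(fwd), hash(revcomp))`` for the k-mer starting at ``i`` and
    ``fwd_wins[i]`` is True when the forward reading attained it (ties go
    forward, which only arise for even k).
    """
    fwd, rc, valid = _kmer_code_arrays(seq, k)
    hf = _hash_array(fwd, k)
    hr = _hash_array(rc, k)
    fwd_wins = hf <= hr
    canon = np.where(fwd_wins, hf, hr)
    return canon, fwd_wins, valid


def extract_minimizers(
    seq: str, params: IndexParams
) -> list[tuple[int, int, str]]:
    """Select winnowed minimizers of one sequence.

    For every window of ``w`` consecutive bases, all k-mers attaining the
    window's minimum canonical hash are emitted; a position shared by
    adjacent windows is emitted once.  Returns ``(code, pos, strand)``
    triples sorted by position, where ``code`` is the canonical hash.
    """
    k, w = params.k, params.w
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    canon, fwd_wins, valid = canonical_kmer_hashes(seq, k)
    n = canon.shape[0]
    hashes = np.where(valid, canon, _U64_MAX)

    # wk = k-mers per window; a sequence shorter than w is a single window.
    wk = min(w - k + 1, n)
    win_min = np.lib.stride_tricks.sliding_window_view(hashes, wk).min(axis=1)
    # Position p belongs to windows [p-wk+1, p] clipped to range; it is a
    # minimizer iff some such window's minimum equals hashes[p], i.e. iff the
    # max of those window minima (all <= hashes[p]) reaches hashes[p].
    pad = np.zeros(wk - 1, dtype=np.uint64)
    padded = np.concatenate([pad, win_min, pad])
    reach = np.lib.stride_tricks.sliding_window_view(padded, wk).max(axis=1)
    emit = valid & (reach == hashes)

    out = []
    for p in np.nonzero(emit)[0]:
        out.append(
            (int(canon[p]), int(p), "+" if fwd_wins[p] else "-")
        )
    return out


@dataclass
class MinimizerIndex:
    """Map from minimizer code to its genomic occurrences."""

    params: IndexParams
    table: dict[int, list[MinimizerOccurrence]]
    source: GenomeAssembly

    def lookup(self, code: int) -> list[MinimizerOccurrence]:
        return self.table.get(code, [])

    @property
    def n_codes(self) -> int:
        return len(self.table)

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(genome: GenomeAssembly, params: IndexParams) -> MinimizerIndex:
    """Winnow every genome sequence and collate occurrences by code.

    Occurrence lists are sorted by ``(seq_index, pos)``; sequences shorter
    than k are skipped.
    """
    table: dict[int, list[MinimizerOccurrence]] = {}
    for seq_index, rec in enumerate(genome):
        if len(rec.seq) < params.k:
            continue
        for code, pos, strand in extract_minimizers(rec.seq, params):
            table.setdefault(code, []).append(
                MinimizerOccurrence(seq_index, pos, strand)
            )
    cap = params.max_code_occurrences
    if cap is not None:
        for code in table:
            del table[code][cap:]
    return MinimizerIndex(params=params, table=table, source=genome)
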