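"""Per-TE homology search: k-mer hit collection and colinear chaining.

A library TE is treated like a noisy long read.  Every overlapping k-mer of
the TE (the query side is deliberately not subsampled — only the genome is
winnowed) is looked up in the minimizer index by canonical hash; matching
occurrences become anchors.  Dynamic programming then clusters anchors that
are colinear in query and subject into chains, one chain per putative TE
copy, and each chain's outermost anchor positions become the match
boundaries.  No base-level alignment is ever computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .minimizer_index import MinimizerIndex, canonical_kmer_hashes
from .sequence_io import GenomeAssembly, TEAnnotation, TELibraryEntry

__all__ = [
    "ChainParams",
    "KmerHit",
    "HitChain",
    "collect_hits",
    "chain_hits",
    "chains_to_matches",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainParams:
    """Hit-collection and chaining thresholds.

    max_hits_per_te
        Cap on raw hits retained per library entry before chaining (10,000
        by default), truncated deterministically in genomic order.
    band
        Maximum diagonal drift |Δsubject − Δquery| between consecutive
        chained anchors, in bp.  Absorbs indels between TE copy and library
        consensus.
    max_gap
        Maximum subject-position gap between consecutive chained anchors,
        in bp; keeps distinct nearby copies in separate chains.
    min_chain_hits
        Minimum anchors per reported chain; chains below this are noise.
    """

    max_hits_per_te: int = 10_000
    band: int = 500
    max_gap: int = 1_000
    min_chain_hits: int = 5

    def __post_init__(self) -> None:
        for name in ("max_hits_per_te", "band", "max_gap", "min_chain_hits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class KmerHit:
    """One query k-mer anchored on the genome.

    ``strand`` is '+' when the TE k-mer and the genomic occurrence read in
    the same orientation, '-' when they are reverse complements.
    """

    query_pos: int
    seq_index: int
    subject_pos: int
    strand: str


@dataclass
class HitChain:
    """A colinear cluster of k-mer hits supporting one TE copy.

    ``subject_start``/``subject_end`` span the chain 0-based half-open:
    first anchor start to last anchor start + k.
    """

    hits: list[KmerHit]
    seq_index: int
    strand: str
    subject_start: int
    subject_end: int

    @property
    def support(self) -> int:
        return len(self.hits)


def collect_hits(
    te: TELibraryEntry, index: MinimizerIndex, params: ChainParams
) -> list[KmerHit]:
    """Match every overlapping k-mer of ``te`` against the genome index.

    Hits are sorted by (seq_index, subject_pos, query_pos) and truncated to
    ``max_hits_per_te`` in that order.  A TE shorter than k yields no hits.
    """
    k = index.params.k
    if len(te.seq) < k:
        logger.warning("library entry %s shorter than k=%d; skipped", te.id, k)
        return []
    canon, fwd_wins, valid = canonical_kmer_hashes(te.seq, k)
    hits: list[KmerHit] = []
    for qpos in np.nonzero(valid)[0]:
        occs = index.lookup(int(canon[qpos]))
        if not occs:
            continue
        q_fwd = bool(fwd_wins[qpos])
        for occ in occs:
            same = (occ.strand == "+") == q_fwd
            hits.append(
                KmerHit(int(qpos), occ.seq_index, occ.pos, "+" if same else "-")
            )
    hits.sort(key=lambda h: (h.seq_index, h.subject_pos, h.query_pos))
    if len(hits) > params.max_hits_per_te:
        hits = hits[: params.max_hits_per_te]
    return hits


def _best_chain(sub: np.ndarray, qry: np.ndarray, sign: int,
                params: ChainParams) -> list[int]:
    """Highest-scoring colinear chain over one (seq, strand) hit group.

    Hit j extends hit i iff subject strictly increases, query strictly
    advances in the strand's direction, the subject gap is <= max_gap and
    the diagonal drift |Δsubject − Δquery| is <= band.  Score is the anchor
    count.  Returns indices of the best chain (ties: earliest end, then
    leftmost predecessors, deterministically).
    """
    n = sub.shape[0]
    dp = np.ones(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    for j in range(1, n):
        lo = int(np.searchsorted(sub, sub[j] - params.max_gap, side="left"))
        if lo >= j:
            continue
        ds = sub[j] - sub[lo:j]
        dq = sign * (qry[j] - qry[lo:j])
        ok = (ds > 0) & (dq > 0) & (np.abs(ds - dq) <= params.band)
        if not ok.any():
            continue
        cand = dp[lo:j].copy()
        cand[~ok] = 0
        best = int(cand.argmax())  # ties -> leftmost predecessor
        if cand[best] > 0:
            dp[j] = cand[best] + 1
            prev[j] = lo + best
    end = int(dp.argmax())  # ties -> earliest chain end
    chain = []
    while end >= 0:
        chain.append(end)
        end = int(prev[end])
    chain.reverse()
    return chain


def chain_hits(
    hits: list[KmerHit], params: ChainParams, k: int = 15
) -> list[HitChain]:
    """Cluster one TE's hits into colinear chains by dynamic programming.

    Hits are partitioned by (seq_index, strand); within each group the best
    chain is extracted, its hits removed, and the DP repeated on the
    remainder (highest score first, each hit used once) until no chain
    reaches ``min_chain_hits``.
    """
    groups: dict[tuple[int, str], list[KmerHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_index, h.strand), []).append(h)

    chains: list[HitChain] = []
    for (seq_index, strand) in sorted(groups):
        group = sorted(
            groups[(seq_index, strand)],
            key=lambda h: (h.subject_pos, h.query_pos),
        )
        sign = 1 if strand == "+" else -1
        while group:
            sub = np.array([h.subject_pos for h in group], dtype=np.int64)
            qry = np.array([h.query_pos for h in group], dtype=np.int64)
            idx = _best_chain(sub, qry, sign, params)
            if len(idx) < params.min_chain_hits:
                break
            chosen = [group[i] for i in idx]
            chains.append(
                HitChain(
                    hits=chosen,
                    seq_index=seq_index,
                    strand=strand,
                    subject_start=chosen[0].subject_pos,
                    subject_end=chosen[-1].subject_pos + k,
                )
            )
            used = set(idx)
            group = [h for i, h in enumerate(group) if i not in used]
    chains.sort(key=lambda c: (c.seq_index, c.subject_start, c.strand))
    return chains


def chains_to_matches(
    chains: list[HitChain], te: TELibraryEntry, genome: GenomeAssembly
) -> list[TEAnnotation]:
    """Convert chains to annotations: chain span -> 1-based inclusive interval.

    The first clustered anchor's start and the last clustered anchor's end
    become the match boundaries; no alignment refinement is attempted.
    """
    matches = []
    for c in chains:
        seq_name = genome.records[c.seq_index].name
        matches.append(
            TEAnnotation(
                seq_name=seq_name,
                first=c.subject_start + 1,
                last=min(c.subject_end, len(genome.records[c.seq_index])),
                family=te.family,
                source_id=te.id,
                support=c.support,
            )
        )
    return matches
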