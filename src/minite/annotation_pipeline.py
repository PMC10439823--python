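"""Full annotation pipeline: per-TE search, merging and iterative rounds.

One round searches every library entry against the (fixed) genome minimizer
index and merges overlapping matches into single annotations.  Because a
curated library rarely covers the full diversity of a genome's TE families,
subsequent rounds re-search with the library augmented by the genomic
sequences of the previous round's annotations, trading runtime for
sensitivity.  Two rounds is the default.  Annotations shorter than
``min_te_length`` (200 bp by default — shorter intervals are likely
annotation noise) are dropped after the final round only, so short fragments
can still seed later-round discoveries.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .homology_search import (
    ChainParams,
    chain_hits,
    chains_to_matches,
    collect_hits,
)
from .minimizer_index import IndexParams, MinimizerIndex, build_index
from .sequence_io import GenomeAssembly, TEAnnotation, TELibraryEntry

__all__ = [
    "PipelineParams",
    "merge_annotations",
    "annotate_round",
    "extract_annotated_sequences",
    "annotate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """End-to-end annotation parameters.

    The pipeline is fully deterministic: identical inputs and parameters
    give identical output at any thread count.
    """

    iterations: int = 2
    min_te_length: int = 200
    chain: ChainParams = field(default_factory=ChainParams)
    index: IndexParams = field(default_factory=IndexParams)
    threads: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.min_te_length < 0:
            raise ValueError("min_te_length must be >= 0")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


def merge_annotations(annotations: list[TEAnnotation]) -> list[TEAnnotation]:
    """Merge overlapping matches on each sequence into single annotations.

    Output intervals are the connected components of the overlap graph
    (sharing >= 1 bp, 1-based inclusive): span = [min first, max last],
    support = sum of constituent supports, family = family of the
    constituent with the greatest support (ties: lexicographically smallest
    family).  Result is sorted by (seq_name, first) and non-overlapping.
    """
    merged: list[TEAnnotation] = []
    ordered = sorted(annotations, key=lambda a: (a.seq_name, a.first, a.last))
    cluster: list[TEAnnotation] = []

    def flush() -> None:
        if not cluster:
            return
        rep = min(cluster, key=lambda a: (-a.support, a.family))
        merged.append(
            TEAnnotation(
                seq_name=cluster[0].seq_name,
                first=min(a.first for a in cluster),
                last=max(a.last for a in cluster),
                family=rep.family,
                source_id=rep.source_id,
                support=sum(a.support for a in cluster),
            )
        )

    cur_end = 0
    for a in ordered:
        if cluster and a.seq_name == cluster[0].seq_name and a.first <= cur_end:
            cluster.append(a)
            cur_end = max(cur_end, a.last)
        else:
            flush()
            cluster = [a]
            cur_end = a.last
    flush()
    return merged


def _search_one(
    te: TELibraryEntry,
    index: MinimizerIndex,
    genome: GenomeAssembly,
    chain_params: ChainParams,
) -> list[TEAnnotation]:
    hits = collect_hits(te, index, chain_params)
    chains = chain_hits(hits, chain_params, k=index.params.k)
    return chains_to_matches(chains, te, genome)


def annotate_round(
    genome: GenomeAssembly,
    index: MinimizerIndex,
    library: list[TELibraryEntry],
    params: PipelineParams,
) -> list[TEAnnotation]:
    """One search round: every library entry mapped, all matches merged.

    Library entries are searched independently (concurrently when
    ``params.threads`` > 1); results are gathered in library order before
    merging, so output is identical at any thread count.
    """
    if not library:
        logger.warning("empty TE library; nothing to annotate")
        return []
    if params.threads > 1:
        with ThreadPoolExecutor(max_workers=params.threads) as pool:
            per_te = list(
                pool.map(
                    lambda te: _search_one(te, index, genome, params.chain),
                    library,
                )
            )
    else:
        per_te = [
            _search_one(te, index, genome, params.chain) for te in library
        ]
    raw = [m for matches in per_te for m in matches]
    merged = merge_annotations(raw)
    logger.info(
        "round: %d entries searched, %d raw matches, %d merged "
        "annotations, %d bp annotated",
        len(library), len(raw), len(merged), sum(a.length for a in merged),
    )
    return merged


def extract_annotated_sequences(
    genome: GenomeAssembly, annotations: list[TEAnnotation]
) -> list[TELibraryEntry]:
    """Turn annotations into library entries for the next search round.

    Each entry is the forward-strand genomic substring of its annotation,
    id ``{seq_name}_{first}_{last}``, family inherited.
    """
    entries = []
    for a in annotations:
        seq = genome.get(a.seq_name).seq[a.first - 1:a.last]
        entries.append(
            TELibraryEntry(
                id=f"{a.seq_name}_{a.first}_{a.last}",
                family=a.family,
                seq=seq,
            )
        )
    return entries


def annotate(
    genome: GenomeAssembly,
    library: list[TELibraryEntry],
    params: PipelineParams | None = None,
) -> list[TEAnnotation]:
    """Annotate a genome against a curated TE library.

    The minimizer index is built once and reused across rounds (only the
    library changes).  Round 1 searches the curated library; each later
    round searches the curated library plus the previous round's annotated
    genomic sequences.  The final round's merged annotations, filtered to
    ``min_te_length``, are returned.
    """
    if params is None:
        params = PipelineParams()
    index = build_index(genome, params.index)
    logger.info(
        "indexed %d sequence(s), %d bp: %d minimizer codes, %d occurrences",
        len(genome), genome.total_length, index.n_codes, index.n_occurrences,
    )
    current_library = list(library)
    annotations: list[TEAnnotation] = []
    for round_no in range(1, params.iterations + 1):
        annotations = annotate_round(genome, index, current_library, params)
        if round_no < params.iterations:
            extracted = extract_annotated_sequences(genome, annotations)
            seen: set[str] = set()
            unique = [
                e for e in extracted
                if not (e.id in seen or seen.add(e.id))
            ]
            current_library = list(library) + unique
    final = [a for a in annotations if a.length >= params.min_te_length]
    logger.info(
        "final: %d annotations, %d bp (min length %d bp)",
        len(final), sum(a.length for a in final), params.min_te_length,
    )
    return final
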