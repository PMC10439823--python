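"""Seeded synthetic repeat genomes with ground-truth annotations.

The generator emulates the structure of a repeat-rich plant assembly at
desk scale: a random background chromosome into which mutated, truncated
and (optionally) nested copies of a small set of TE consensus sequences are
*inserted* — insertion rather than replacement, because real TE copies are
insertion events, and it is what makes nesting well-defined.  Every
insertion shifts all previously recorded coordinates to its right, and
growing an outer copy by inserting inside it enlarges that copy's recorded
interval, so the ground truth always reflects final coordinates.

Each copy's provenance (family, strand, effective substitution count,
truncation) is recorded alongside the truth interval, which lets tests
verify the coordinate bookkeeping base by base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region_compare import ComparisonResult, compare_region_sets
from .sequence_io import (
    GenomeAssembly,
    SequenceRecord,
    TEAnnotation,
    TELibraryEntry,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCopy",
    "SimulatedDataset",
    "simulate",
    "evaluate_against_truth",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

# Superfamily labels cycled over simulated families, echoing the
# class/superfamily/lineage hierarchy of curated plant TE libraries.
_SUPERFAMILIES = ("LTR/Gypsy", "LTR/Copia", "DNA/CACTA", "LINE/L1",
                  "DNA/Mutator")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated dataset.

    Defaults describe a desk-scale repeat genome: a 100 kb background at
    40% GC carrying a handful of kb-scale TE families with moderately
    divergent copies on both strands.
    """

    seed: int = 0
    genome_length: int = 100_000
    gc_content: float = 0.4
    n_families: int = 3
    te_length_range: tuple[int, int] = (1_000, 4_000)
    n_copies_per_family: int = 5
    substitution_rate: float = 0.05
    indel_rate: float = 0.005
    truncation_prob: float = 0.2
    nesting_prob: float = 0.1
    minus_strand_prob: float = 0.5
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        for name in ("gc_content", "substitution_rate", "indel_rate",
                     "truncation_prob", "nesting_prob", "minus_strand_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        n_copies = self.n_families * self.n_copies_per_family
        if self.genome_length <= n_copies * self.te_length_range[1]:
            raise ValueError(
                "genome_length must exceed total TE payload "
                f"({n_copies} copies x {self.te_length_range[1]} bp max)"
            )


@dataclass(frozen=True)
class SimulatedCopy:
    """Provenance of one inserted TE copy."""

    family: str
    source_id: str
    strand: str
    n_substitutions: int
    n_indel_events: int
    truncated: bool
    nested: bool


@dataclass
class SimulatedDataset:
    """A simulated genome, its consensus library and ground truth."""

    genome: GenomeAssembly
    library: list[TELibraryEntry]
    truth: list[TEAnnotation]
    copies: list[SimulatedCopy]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return (np.uint8(3) - arr)[::-1]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset; deterministic given ``config.seed``.

    Each copy is derived as consensus -> optional reverse complement ->
    substitutions -> indels -> optional truncation -> insertion.  Nested
    copies land strictly inside a previously placed copy; plain copies are
    placed (by rejection) outside all existing copies, so non-nested truth
    intervals never overlap.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_seq(rng, config.genome_length, config.gc_content)

    library: list[TELibraryEntry] = []
    consensi: list[np.ndarray] = []
    for i in range(config.n_families):
        length = int(rng.integers(config.te_length_range[0],
                                  config.te_length_range[1] + 1))
        cons = _random_seq(rng, length, config.gc_content)
        family = f"{_SUPERFAMILIES[i % len(_SUPERFAMILIES)]}/Fam{i}"
        library.append(
            TELibraryEntry(id=f"TE_{i:03d}#{family}", family=family,
                           seq=_decode(cons))
        )
        consensi.append(cons)

    # Truth intervals as mutable 0-based half-open [start, end) spans.
    spans: list[list[int]] = []
    meta: list[SimulatedCopy] = []
    for fam_idx in range(config.n_families):
        for _ in range(config.n_copies_per_family):
            copy = consensi[fam_idx].copy()
            strand = "-" if rng.random() < config.minus_strand_prob else "+"
            if strand == "-":
                copy = _revcomp(copy)

            sub_mask = rng.random(copy.shape[0]) < config.substitution_rate
            n_subs = int(sub_mask.sum())
            if n_subs:
                shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
                copy[sub_mask] = (copy[sub_mask] + shift) % np.uint8(4)

            n_indels = 0
            if config.indel_rate > 0:
                sites = np.nonzero(
                    rng.random(copy.shape[0]) < config.indel_rate
                )[0]
                n_indels = len(sites)
                for pos in sites[::-1]:  # right-to-left keeps positions valid
                    length = int(rng.geometric(0.5))  # mean 2
                    if rng.random() < 0.5:
                        ins = _random_seq(rng, length, config.gc_content)
                        copy = np.concatenate([copy[:pos], ins, copy[pos:]])
                    else:
                        copy = np.concatenate([copy[:pos],
                                               copy[pos + length:]])

            truncated = rng.random() < config.truncation_prob
            if truncated:
                frac = rng.uniform(0.25, 1.0)
                keep = max(1, int(round(frac * copy.shape[0])))
                if rng.random() < 0.5:
                    copy = copy[:keep]  # 3' truncation
                else:
                    copy = copy[copy.shape[0] - keep:]  # 5' truncation

            L = copy.shape[0]
            nested = bool(spans) and rng.random() < config.nesting_prob
            nested = nested and any(s[1] - s[0] >= 2 for s in spans)
            if nested:
                hosts = [s for s in spans if s[1] - s[0] >= 2]
                outer = hosts[int(rng.integers(len(hosts)))]
                ip = int(rng.integers(outer[0] + 1, outer[1]))
            else:
                ip = None
                for _attempt in range(1_000):
                    cand = int(rng.integers(0, genome.shape[0] + 1))
                    if all(not (s[0] < cand < s[1]) for s in spans):
                        ip = cand
                        break
                if ip is None:
                    raise RuntimeError(
                        "infeasible packing: no insertion point found"
                    )

            genome = np.concatenate([genome[:ip], copy, genome[ip:]])
            for s in spans:
                if s[0] >= ip:
                    s[0] += L
                    s[1] += L
                elif s[1] > ip:  # insertion inside: outer copy grows
                    s[1] += L
            spans.append([ip, ip + L])
            meta.append(
                SimulatedCopy(
                    family=library[fam_idx].family,
                    source_id=library[fam_idx].id,
                    strand=strand,
                    n_substitutions=n_subs,
                    n_indel_events=n_indels,
                    truncated=truncated,
                    nested=nested,
                )
            )

    truth = [
        TEAnnotation(
            seq_name=config.chrom_name,
            first=s[0] + 1,
            last=s[1],
            family=m.family,
            source_id=m.source_id,
        )
        for s, m in zip(spans, meta)
    ]
    assembly = GenomeAssembly(
        records=[SequenceRecord(config.chrom_name, _decode(genome))]
    )
    return SimulatedDataset(
        genome=assembly, library=library, truth=truth, copies=meta
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> list[str]:
    """Write genome.fa, library.fa and truth.tsv into ``outdir``."""
    import os

    from .sequence_io import write_annotations, write_fasta

    os.makedirs(outdir, exist_ok=True)
    genome_path = os.path.join(outdir, "genome.fa")
    library_path = os.path.join(outdir, "library.fa")
    truth_path = os.path.join(outdir, "truth.tsv")
    write_fasta(dataset.genome.records, genome_path)
    write_fasta(dataset.library, library_path)
    write_annotations(dataset.truth, truth_path)
    return [genome_path, library_path, truth_path]


def evaluate_against_truth(
    predicted: list[TEAnnotation], truth: list[TEAnnotation]
) -> ComparisonResult:
    """Base-pair agreement of predictions with the ground truth.

    ``frac_a_in_b`` is precision, ``frac_b_in_a`` sensitivity.
    """
    return compare_region_sets(predicted, truth)
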