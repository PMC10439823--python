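"""Base-pair overlap comparison between two genome annotation sets.

Given annotation sets A and B, the comparator reports the union size of
each set and, in each direction, the number and fraction of base pairs of
one set's union also covered by the other.  When A is a tool's output and B
a reference annotation, ``frac_a_in_b`` is base-pair precision and
``frac_b_in_a`` base-pair sensitivity; their harmonic mean is the F-score.
Family labels play no role — agreement is purely positional.  All counting
is exact integer arithmetic on interval unions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sequence_io import TEAnnotation

__all__ = [
    "ComparisonResult",
    "compare_region_sets",
    "length_histogram",
    "library_coverage",
    "read_repeatmasker_out",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    """Directional base-pair overlap between two annotation sets."""

    bp_a: int
    bp_b: int
    bp_intersection: int
    frac_a_in_b: float
    frac_b_in_a: float
    f_score: float


def _union(annotations) -> dict[str, list[tuple[int, int]]]:
    """Per-sequence merged (first, last) intervals, 1-based inclusive."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_name, []).append((a.first, a.last))
    out = {}
    for seq, ivs in by_seq.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for first, last in ivs[1:]:
            # adjacent intervals cover the same base set once concatenated
            if first <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], last)
            else:
                merged.append([first, last])
        out[seq] = [(f, l) for f, l in merged]
    return out


def _union_bp(union: dict[str, list[tuple[int, int]]]) -> int:
    return sum(l - f + 1 for ivs in union.values() for f, l in ivs)


def _intersection_bp(
    ua: dict[str, list[tuple[int, int]]],
    ub: dict[str, list[tuple[int, int]]],
) -> int:
    total = 0
    for seq in ua.keys() & ub.keys():
        ia, ib = ua[seq], ub[seq]
        i = j = 0
        while i < len(ia) and j < len(ib):
            lo = max(ia[i][0], ib[j][0])
            hi = min(ia[i][1], ib[j][1])
            if hi >= lo:
                total += hi - lo + 1
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    return total


def compare_region_sets(
    a: list[TEAnnotation], b: list[TEAnnotation]
) -> ComparisonResult:
    """Compute directional base-pair overlap fractions between A and B.

    Sequences present in only one set contribute to that set's union only.
    An empty union yields a fraction of 0 (with a warning) rather than an
    error, for batch-robustness.
    """
    ua, ub = _union(a), _union(b)
    bp_a, bp_b = _union_bp(ua), _union_bp(ub)
    inter = _intersection_bp(ua, ub)
    if bp_a == 0:
        logger.warning("set A covers 0 bp; frac_a_in_b reported as 0")
    if bp_b == 0:
        logger.warning("set B covers 0 bp; frac_b_in_a reported as 0")
    frac_a = inter / bp_a if bp_a else 0.0
    frac_b = inter / bp_b if bp_b else 0.0
    f = (2 * frac_a * frac_b / (frac_a + frac_b)) if (frac_a + frac_b) else 0.0
    return ComparisonResult(bp_a, bp_b, inter, frac_a, frac_b, f)


def length_histogram(
    annotations: list[TEAnnotation], bin_width: int = 200
) -> list[tuple[int, int]]:
    """Histogram of annotation lengths in steps of ``bin_width`` bp.

    Returns ``(bin_start, count)`` pairs for non-empty bins, ascending;
    a length L falls in the bin [bin_start, bin_start + bin_width).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: dict[int, int] = {}
    for a in annotations:
        b = (a.length // bin_width) * bin_width
        counts[b] = counts.get(b, 0) + 1
    return sorted(counts.items())


def library_coverage(
    annotations: list[TEAnnotation], truth: list[TEAnnotation]
) -> list[tuple[float, float]]:
    """Per-element coverage of reference intervals by single annotations.

    For each ``truth`` element, the best (maximum-overlap) single annotation
    is found; returned per element are (overlap / truth length,
    overlap / best annotation's length), both 0 when nothing overlaps.
    """
    by_seq: dict[str, list[TEAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_name, []).append(a)
    out = []
    for t in truth:
        best_ov, best_len = 0, 0
        for a in by_seq.get(t.seq_name, []):
            ov = min(t.last, a.last) - max(t.first, a.first) + 1
            if ov > best_ov:
                best_ov, best_len = ov, a.length
        out.append(
            (best_ov / t.length if best_ov else 0.0,
             best_ov / best_len if best_ov else 0.0)
        )
    return out


def read_repeatmasker_out(path) -> list[TEAnnotation]:
    """Read a RepeatMasker .out table into annotations.

    Space-delimited with 3 header lines; columns 5-7 hold sequence name and
    1-based begin/end, column 11 the repeat class/family.
    """
    annotations = []
    with open(path) as fh:
        lines = fh.readlines()[3:]
    for line in lines:
        fields = line.split()
        if len(fields) < 11:
            continue
        annotations.append(
            TEAnnotation(
                seq_name=fields[4],
                first=int(fields[5]),
                last=int(fields[6]),
                family=fields[10],
            )
        )
    return annotations
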