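"""Genome masking from an annotation table.

Soft masking lowercases every base inside an annotated interval; hard
masking replaces it with 'N'.  Sequence names, order and lengths are always
preserved, pre-existing lowercase outside the annotations is left alone, and
overlapping annotations apply idempotently.
"""

from __future__ import annotations

from .sequence_io import GenomeAssembly, SequenceRecord, TEAnnotation

__all__ = ["mask_genome", "MASK_MODES"]

MASK_MODES = ("soft", "hard")


def mask_genome(
    genome: GenomeAssembly,
    annotations: list[TEAnnotation],
    mode: str = "soft",
) -> GenomeAssembly:
    """Return a copy of ``genome`` with annotated intervals masked.

    ``mode`` is ``"soft"`` (lowercase) or ``"hard"`` ('N').  Raises
    ``ValueError`` when an annotation names an unknown sequence or falls
    outside its bounds, identifying the offending annotation.
    """
    if mode not in MASK_MODES:
        raise ValueError(f"mode must be one of {MASK_MODES}, got {mode!r}")
    buffers: dict[str, bytearray] = {
        r.name: bytearray(r.seq, "ascii") for r in genome
    }
    for i, a in enumerate(annotations, start=1):
        if a.seq_name not in buffers:
            raise ValueError(
                f"annotation {i} ({a.seq_name}:{a.first}-{a.last}): "
                f"unknown sequence '{a.seq_name}'"
            )
        buf = buffers[a.seq_name]
        if a.last > len(buf):
            raise ValueError(
                f"annotation {i} ({a.seq_name}:{a.first}-{a.last}): "
                f"interval exceeds sequence length {len(buf)}"
            )
        if mode == "soft":
            buf[a.first - 1:a.last] = buf[a.first - 1:a.last].lower()
        else:
            buf[a.first - 1:a.last] = b"N" * (a.last - a.first + 1)
    return GenomeAssembly(
        records=[
            SequenceRecord(r.name, buffers[r.name].decode("ascii"),
                           r.description)
            for r in genome
        ]
    )
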