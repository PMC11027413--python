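"""Small strand-aware coordinate helpers.

All internal coordinates are 0-based half-open. "Upstream"/"downstream" always
refer to the transcription sense of the gene under consideration, so a window
"300 bp upstream of the TSS" of a minus-strand gene lies genomically to the
right of its TSS.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def sense_window(anchor: int, strand: str, start_off: int, end_off: int) -> tuple[int, int]:
    """Genomic half-open interval covering transcript-sense offsets
    ``[start_off, end_off)`` relative to ``anchor``.

    Offsets increase 5'->3' along the gene; negative offsets are upstream.
    """
    if end_off <= start_off:
        raise ValueError(f"empty sense window [{start_off}, {end_off})")
    if strand == "+":
        return anchor + start_off, anchor + end_off
    if strand == "-":
        return anchor - end_off, anchor - start_off
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def opposite(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")
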