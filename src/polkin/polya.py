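"""polyA-site calling from 3'-end sequencing read ends.

Read 3'-end positions (transcript sense) are single-linkage clustered per
chromosome and strand, merging ends within 30 bp. Clusters whose transcript
sense downstream sequence carries a run of ten or more genomic As are flagged
as internal-priming (misprime) artifacts and excluded from the final site
list. Canonical polyadenylation signals (AWTAAA) are annotated upstream of
each summit, together with downstream G/T richness.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .genomic import reverse_complement

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "[AT]", "S": "[CG]",
         "R": "[AG]", "Y": "[CT]", "K": "[GT]", "M": "[AC]", "N": "[ACGT]",
         "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]"}


class EndRead(NamedTuple):
    chrom: str
    strand: str
    end_pos: int  # genomic position of the read 3' end (0-based)


@dataclass
class PolyAPeak:
    chrom: str
    strand: str
    start: int   # half-open span of clustered ends
    end: int
    summit: int  # modal end position
    count: int
    misprime: bool = False
    motifs: list[tuple[str, int]] = field(default_factory=list)


def read_end_bed(path) -> list[EndRead]:
    """BED6 of single-base read 3'-end positions (name/score ignored)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 required "
                                 f"(strand field is mandatory)")
            reads.append(EndRead(f[0], f[5], int(f[1])))
    return reads


def write_end_bed(reads: Iterable[EndRead], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(sorted(reads)):
            fh.write(f"{r.chrom}\t{r.end_pos}\t{r.end_pos + 1}\tend{i}\t0\t{r.strand}\n")


def write_peak_bed(peaks: Iterable[PolyAPeak], path) -> None:
    """BED6 of called sites; score carries the read count, name the summit."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.strand)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tsummit={p.summit}"
                     f"\t{p.count}\t{p.strand}\n")


def cluster_read_ends(reads: Sequence[EndRead], merge_dist: int = 30) -> list[PolyAPeak]:
    """Single-linkage clustering of read ends per chromosome and strand.

    Consecutive end positions at most ``merge_dist`` bp apart join one peak.
    The summit is the modal end position; ties go to the 5'-most position in
    transcript sense. Output is sorted by (chrom, start, strand).
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        if r.strand not in "+-":
            raise ValueError(f"read strand must be '+' or '-', got {r.strand!r}")
        groups.setdefault((r.chrom, r.strand), []).append(r.end_pos)

    peaks = []
    for (chrom, strand), positions in groups.items():
        positions.sort()
        cluster = [positions[0]]
        for pos in positions[1:]:
            if pos - cluster[-1] <= merge_dist:
                cluster.append(pos)
            else:
                peaks.append(_make_peak(chrom, strand, cluster))
                cluster = [pos]
        peaks.append(_make_peak(chrom, strand, cluster))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.strand))
    return peaks


def _make_peak(chrom: str, strand: str, members: list[int]) -> PolyAPeak:
    counts = Counter(members)
    top = max(counts.values())
    tied = [p for p, c in counts.items() if c == top]
    summit = min(tied) if strand == "+" else max(tied)
    return PolyAPeak(chrom=chrom, strand=strand, start=members[0],
                     end=members[-1] + 1, summit=summit, count=len(members))


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Upper-case genomic sequence [start, end), clipped at chromosome edges."""
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"sequence unavailable for {chrom}:{start}-{end}") from None
    text = str(seq[max(0, start):max(0, end)])
    return text.upper()


def sense_sequence(genome, chrom: str, strand: str, origin: int,
                   start_off: int, end_off: int) -> str:
    """Transcript-sense sequence covering offsets [start_off, end_off) from
    ``origin`` (offset 0 = the base at ``origin``)."""
    if strand == "+":
        return _fetch(genome, chrom, origin + start_off, origin + end_off)
    return reverse_complement(_fetch(genome, chrom, origin - end_off + 1,
                                     origin - start_off + 1))


def filter_misprime(peaks: Iterable[PolyAPeak], genome, min_a: int = 10,
                    window: int = 20) -> tuple[list[PolyAPeak], list[PolyAPeak]]:
    """Flag internal-priming peaks and return (all annotated, retained).

    A peak is a misprime when the ``window`` bp transcript-sense downstream of
    its 3' edge contain ``min_a`` or more consecutive As (i.e. Ts read off the
    minus genomic strand for minus-strand peaks). Windows are clipped at
    chromosome edges.
    """
    run = re.compile("A" * min_a)
    annotated, kept = [], []
    for p in peaks:
        edge = p.end - 1 if p.strand == "+" else p.start
        seq = sense_sequence(genome, p.chrom, p.strand, edge, 1, 1 + window)
        p.misprime = bool(run.search(seq))
        annotated.append(p)
        if not p.misprime:
            kept.append(p)
    return annotated, kept


def motif_regex(motif: str) -> re.Pattern:
    return re.compile("".join(IUPAC[b] for b in motif.upper()))


def scan_polya_signal(peak: PolyAPeak, genome, motifs: Sequence[str] = ("AWTAAA",),
                      search: tuple[int, int] = (-50, 0),
                      gt_window: tuple[int, int] = (0, 30)) -> dict:
    """Annotate polyadenylation-signal motifs around a peak summit.

    Motifs (IUPAC strings) are matched on the transcript-sense sequence over
    ``search`` offsets from the summit; hits are (motif, offset) with offset
    the motif start relative to the summit. Downstream G/T richness — the
    fraction of G or T bases over ``gt_window`` — is reported alongside (a
    plain composition statistic, not a positional motif model).
    """
    lo, hi = search
    seq = sense_sequence(genome, peak.chrom, peak.strand, peak.summit, lo, hi)
    hits = []
    for m in motifs:
        for match in motif_regex(m).finditer(seq):
            hits.append((m, match.start() + lo))
    g_lo, g_hi = gt_window
    down = sense_sequence(genome, peak.chrom, peak.strand, peak.summit, g_lo, g_hi)
    gt_fraction = (sum(b in "GT" for b in down) / len(down)) if down else 0.0
    peak.motifs = hits
    return {"hits": hits, "gt_fraction": gt_fraction}
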