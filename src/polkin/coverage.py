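"""Strand-resolved per-base coverage tracks and the binned views built on them.

A :class:`CoverageTrack` holds dense per-base arrays per chromosome; a
:class:`StrandedCoverage` pairs a plus- and a minus-strand track (a single
unstranded ChIP track can answer both strand queries). Densities are
signal per bp; rpm normalization rescales by 1e6 / library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .genomic import sense_window


class CoverageTrack:
    """Dense per-base signal over a genome, one array per chromosome."""

    def __init__(self, data: Mapping[str, np.ndarray], strand: str = ".",
                 library_size: float | None = None, normalized: bool = False):
        self.data = {c: np.asarray(a, dtype=float) for c, a in data.items()}
        for c, a in self.data.items():
            if (a < 0).any():
                raise ValueError(f"negative signal on {c}")
        self.strand = strand
        self.library_size = library_size
        self.normalized = normalized

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end), zero-padded where the interval
        overruns the chromosome (with a warning)."""
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} not present in track")
        arr = self.data[chrom]
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        lo, hi = max(0, start), min(len(arr), end)
        if lo != start or hi != end:
            warnings.warn(f"interval [{start},{end}) clipped to chromosome "
                          f"{chrom} bounds [0,{len(arr)})")
        out = np.zeros(end - start, dtype=float)
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack({c: a * factor for c, a in self.data.items()},
                             strand=self.strand, library_size=self.library_size,
                             normalized=self.normalized)


@dataclass
class StrandedCoverage:
    """A plus/minus pair of coverage tracks."""

    plus: CoverageTrack
    minus: CoverageTrack

    @classmethod
    def from_unstranded(cls, track: CoverageTrack) -> "StrandedCoverage":
        """An unstranded track (e.g. ChIP) answers both strand queries."""
        return cls(plus=track, minus=track)

    def sense(self, strand: str) -> CoverageTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def antisense(self, strand: str) -> CoverageTrack:
        return self.sense("-" if strand == "+" else "+")

    def scaled(self, factor: float) -> "StrandedCoverage":
        if self.plus is self.minus:
            return StrandedCoverage.from_unstranded(self.plus.scaled(factor))
        return StrandedCoverage(self.plus.scaled(factor), self.minus.scaled(factor))


def _sense_track(cov, strand: str) -> CoverageTrack:
    return cov.sense(strand) if isinstance(cov, StrandedCoverage) else cov


def load_bedgraph(path, strand: str = ".", library_size: float | None = None,
                  chrom_sizes: Mapping[str, int] | None = None) -> CoverageTrack:
    """Read a bedGraph file into a dense track.

    Overlapping intervals are an error (the signal would be ambiguous). With
    ``chrom_sizes`` given, chromosomes absent from the file come back as
    all-zero arrays of the stated length.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            if v < 0:
                raise ValueError(f"{path}: negative value on line {lineno}")
            intervals.setdefault(chrom, []).append((s, e, v))

    data: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph intervals on "
                                 f"{chrom} at {s2} < {e1}")
        n = chrom_sizes[chrom] if chrom_sizes else ivs[-1][1]
        arr = np.zeros(n, dtype=float)
        for s, e, v in ivs:
            arr[s:min(e, n)] = v
        data[chrom] = arr
    if chrom_sizes:
        for chrom, n in chrom_sizes.items():
            data.setdefault(chrom, np.zeros(n, dtype=float))
    return CoverageTrack(data, strand=strand, library_size=library_size)


def load_bigwig(path, strand: str = ".",
                library_size: float | None = None) -> CoverageTrack:
    """Read a bigWig file into a dense track (NaN treated as zero)."""
    import pyBigWig  # deferred: only needed for bigWig inputs

    bw = pyBigWig.open(str(path))
    try:
        data = {}
        for chrom, n in bw.chroms().items():
            vals = np.array(bw.values(chrom, 0, n), dtype=float)
            data[chrom] = np.nan_to_num(vals)
    finally:
        bw.close()
    return CoverageTrack(data, strand=strand, library_size=library_size)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a dense track as bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, n = line.split()[:2]
                sizes[chrom] = int(n)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Scale to reads per million of the library size (rpm)."""
    if track.normalized:
        raise ValueError("track already rpm-normalized")
    if not track.library_size or track.library_size <= 0:
        raise ValueError("library_size must be positive for rpm normalization")
    out = track.scaled(1e6 / track.library_size)
    out.normalized = True
    return out


def interval_density(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean per-base signal over [start, end) (clipped length used)."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    vals = track.query(chrom, start, end)
    return float(vals.sum() / (end - start))


def bin_signal(track: CoverageTrack, chrom: str, anchor: int, strand: str,
               upstream: int, downstream: int, bin_size: int) -> np.ndarray:
    """Gene-strand-oriented vector of per-bin mean densities around ``anchor``.

    Index 0 is the most 5' bin (``upstream`` bp before the anchor in
    transcription sense); bins advance 5'->3'.
    """
    span = upstream + downstream
    if span % bin_size:
        raise ValueError("upstream+downstream must be divisible by bin_size")
    arr = track.data.get(chrom)
    if arr is None:
        raise KeyError(f"chromosome {chrom!r} not present in track")
    if not (0 <= anchor <= len(arr)):
        raise ValueError(f"anchor {anchor} outside chromosome {chrom} [0,{len(arr)}]")
    lo, hi = sense_window(anchor, strand, -upstream, downstream)
    vals = track.query(chrom, lo, hi)
    if strand == "-":
        vals = vals[::-1]
    return vals.reshape(-1, bin_size).mean(axis=1)


def metagene_matrix(cov, genes: Sequence[GeneModel], anchor: str = "TSS",
                    upstream: int = 0, downstream: int = 80_000,
                    bin_size: int = 50) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-gene binned signal (rows 5'->3') plus the column-mean profile.

    ``anchor`` is ``"TSS"`` or ``"TES"``. Genes on chromosomes absent from the
    track are skipped with a warning.
    """
    if len(genes) == 0:
        raise ValueError("metagene_matrix requires at least one gene")
    rows, ids = [], []
    for g in genes:
        track = _sense_track(cov, g.strand)
        if g.chrom not in track.data:
            warnings.warn(f"gene {g.gene_id}: chromosome {g.chrom} missing from track; skipped")
            continue
        pos = g.tss if anchor.upper() == "TSS" else g.tes
        rows.append(bin_signal(track, g.chrom, pos, g.strand, upstream,
                               downstream, bin_size))
        ids.append(g.gene_id)
    if not rows:
        raise ValueError("no gene overlapped the track")
    mat = pd.DataFrame(np.vstack(rows), index=ids)
    return mat, mat.to_numpy().mean(axis=0)
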