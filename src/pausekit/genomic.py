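"""Gene models, interval sets and per-base coverage tracks.

All coordinates are 0-based half-open (BED convention). Coverage is held as a
dense float64 array per chromosome; toy genomes here are tens of Mb at most, so
a dense backend is the simplest contract that every downstream window statistic
can rely on. Parsers are strict: malformed records raise with a line number
rather than being repaired.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "Site",
    "SiteSet",
    "CoverageTrack",
    "BedParseError",
    "TrackError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "window_density",
    "scale_track",
    "normalize_to_total",
]


class BedParseError(ValueError):
    """Malformed BED/bedGraph record; message carries the 1-based line number."""


class TrackError(ValueError):
    """Inconsistent coverage-track operation (overlap, out-of-bounds window...)."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval anchoring TSS/TES.

    TSS is ``start`` on the + strand and ``end - 1`` on the − strand; TES is the
    opposite end (both inclusive base positions).
    """

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Site:
    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"site: need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SiteSet:
    """A sorted collection of genomic intervals (binding sites, peaks...)."""

    sites: tuple[Site, ...]

    def __init__(self, sites: Iterable[Site]):
        ordered = tuple(sorted(sites, key=lambda s: (s.chrom, s.start, s.end)))
        object.__setattr__(self, "sites", ordered)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


class CoverageTrack:
    """Dense per-base non-negative signal over one or more chromosomes."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 1:
                raise TrackError(f"{chrom}: coverage must be 1-D")
            if arr.size and arr.min() < 0:
                raise TrackError(f"{chrom}: negative coverage values")
            clean[chrom] = arr
        self._data = clean

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(int(n)) for c, n in chrom_sizes.items()})

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: a.size for c, a in self._data.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def values(self, chrom: str) -> np.ndarray:
        if chrom not in self._data:
            raise TrackError(f"unknown chromosome {chrom!r}")
        return self._data[chrom]

    @property
    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self._data.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.chroms == other.chroms and all(
            np.array_equal(self._data[c], other._data[c]) for c in self._data
        )


# ---------------------------------------------------------------------------
# BED / chrom.sizes I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | os.PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise BedParseError(f"line {lineno}: non-integer {what} {text!r}") from None


def read_bed(path: str | os.PathLike) -> list[GeneModel] | SiteSet:
    """Read BED3 (→ :class:`SiteSet`) or BED6 (→ list of :class:`GeneModel`).

    Comment/track/browser lines are skipped; anything malformed raises
    :class:`BedParseError` with its line number. Mixed column counts are an
    error.
    """
    genes: list[GeneModel] = []
    sites: list[Site] = []
    ncols: int | None = None
    seen_ids: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) not in (3, 6):
            raise BedParseError(f"line {lineno}: expected 3 or 6 tab-separated columns, got {len(fields)}")
        if ncols is None:
            ncols = len(fields)
        elif len(fields) != ncols:
            raise BedParseError(f"line {lineno}: mixed BED3/BED6 records")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if start >= end or start < 0:
            raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
        if ncols == 3:
            sites.append(Site(chrom, start, end))
        else:
            gene_id, _score, strand = fields[3], fields[4], fields[5]
            if strand not in ("+", "-"):
                raise BedParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            if gene_id in seen_ids:
                raise BedParseError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(GeneModel(chrom, start, end, gene_id, strand))
    if ncols == 3:
        return SiteSet(sites)
    return genes


def write_bed(objects: Sequence[GeneModel] | SiteSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        if isinstance(objects, SiteSet):
            for s in objects:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\n")
        else:
            for g in objects:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise BedParseError(f"line {lineno}: chrom.sizes needs 2 columns")
        size = _parse_int(fields[1], "size", lineno)
        if size <= 0:
            raise BedParseError(f"line {lineno}: non-positive chromosome size")
        sizes[fields[0]] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense track; unspecified bases are 0.

    Overlapping intervals, negative values and intervals outside the declared
    chromosome bounds are errors, not repairs.
    """
    track = CoverageTrack.zeros(chrom_sizes)
    covered: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_sizes}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise BedParseError(f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}")
        chrom = fields[0]
        if chrom not in chrom_sizes:
            raise BedParseError(f"line {lineno}: unknown chromosome {chrom!r}")
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        try:
            value = float(fields[3])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric value {fields[3]!r}") from None
        if start >= end or start < 0:
            raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
        if end > chrom_sizes[chrom]:
            raise BedParseError(
                f"line {lineno}: interval end {end} beyond {chrom} size {chrom_sizes[chrom]}"
            )
        if value < 0:
            raise BedParseError(f"line {lineno}: negative coverage value {value}")
        covered[chrom].append((start, end, lineno))
        track.values(chrom)[start:end] = value
    for chrom, spans in covered.items():
        spans.sort()
        for (s0, e0, _l0), (s1, _e1, l1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise BedParseError(f"line {l1}: interval overlaps a previous record on {chrom}")
    return track


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write run-length-merged bedGraph; zero runs are omitted (implicit 0)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals = track.values(chrom)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Windowed densities and normalization
# ---------------------------------------------------------------------------

def window_density(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean signal per base over ``[start, end)``; out-of-bounds windows raise."""
    vals = track.values(chrom)
    if not (0 <= start < end <= vals.size):
        raise TrackError(
            f"window [{start}, {end}) outside {chrom} (length {vals.size})"
        )
    return float(vals[start:end].sum() / (end - start))


def scale_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    if factor < 0:
        raise TrackError("scale factor must be non-negative")
    return CoverageTrack({c: track.values(c) * factor for c in track.chroms})


def normalize_to_total(track: CoverageTrack, target_total: float = 1e7) -> CoverageTrack:
    """Rescale so the genome-wide total equals ``target_total``.

    The default target (counts-per-ten-million equivalents) puts conditions on a
    common footing before traveling-ratio or metagene comparison.
    """
    total = track.total_signal
    if total <= 0:
        raise TrackError("cannot normalize an all-zero track")
    return scale_track(track, target_total / total)
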