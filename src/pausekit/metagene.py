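"""Anchor-centered average profiles, occupancy heatmaps and profile ratios.

A metagene profile averages coverage around many anchors (TSSs of genes or
midpoints of binding sites) as a function of distance from the anchor; the
occupancy heatmap keeps the per-anchor rows. pS2 (elongating RNAP2) profiles
are normalized bin-wise to total-RNAP2 profiles to compare elongation across
conditions, and per-site binding densities of two factors are correlated on a
log scale.

Anchor rows are always reduced in one canonical order (descending row mean,
ties by anchor id), so the column means of the occupancy matrix reproduce the
metagene profile exactly, to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import CoverageTrack, GeneModel, SiteSet, window_density

__all__ = [
    "MetageneProfile",
    "OccupancyMatrix",
    "RatioProfile",
    "ConcordanceResult",
    "metagene_profile",
    "occupancy_heatmap",
    "scaled_gene_profile",
    "normalize_profiles",
    "site_density_concordance",
    "mean_profile_summary",
]

#: pseudocount added before log10 in density concordance (densities are
#: right-skewed; the floor keeps empty sites finite)
LOG_DENSITY_PSEUDOCOUNT = 1e-3


@dataclass
class MetageneProfile:
    """Mean density per bin around an anchor set."""

    values: np.ndarray
    flank: int
    bin_size: int
    n_anchors: int
    anchor_label: str = ""
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_offsets(self) -> np.ndarray:
        """Offset of each bin center from the anchor (bp)."""
        return -self.flank + self.bin_size * (np.arange(self.n_bins) + 0.5)


@dataclass
class OccupancyMatrix:
    """Per-anchor binned densities; rows sorted by descending row mean."""

    matrix: pd.DataFrame
    flank: int
    bin_size: int
    n_dropped: int = 0

    def column_means(self) -> np.ndarray:
        return self.matrix.to_numpy().mean(axis=0)


@dataclass
class RatioProfile:
    """Bin-wise ratio of two metagene profiles (e.g. pS2 / total RNAP2)."""

    values: np.ndarray
    flank: int
    bin_size: int
    ratio_pseudocount: float

    @property
    def bin_offsets(self) -> np.ndarray:
        n = self.values.size
        return -self.flank + self.bin_size * (np.arange(n) + 0.5)


@dataclass
class ConcordanceResult:
    """Per-site density pairs of two tracks with their Pearson correlation."""

    densities: pd.DataFrame
    r: float
    p: float
    degenerate: bool
    log_pseudocount: float


def _anchor_points(anchors: SiteSet | list[GeneModel]) -> list[tuple[str, int, str, str]]:
    """(chrom, anchor position, strand, id) per anchor.

    Sites anchor at their midpoint on the + strand; genes anchor at their TSS
    with their own strand.
    """
    out = []
    if isinstance(anchors, SiteSet):
        for s in anchors:
            out.append((s.chrom, s.midpoint, "+", f"{s.chrom}:{s.start}-{s.end}"))
    else:
        for g in anchors:
            out.append((g.chrom, g.tss, g.strand, g.gene_id))
    return out


def _anchor_rows(
    track: CoverageTrack,
    anchors: SiteSet | list[GeneModel],
    flank: int,
    bin_size: int,
    strand_aware: bool,
) -> tuple[list[str], np.ndarray, int]:
    if flank <= 0 or bin_size <= 0 or flank % bin_size != 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    n_bins = 2 * flank // bin_size
    sizes = track.chrom_sizes
    ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for chrom, pos, strand, anchor_id in _anchor_points(anchors):
        # on the − strand the half-open window shifts by one base so that the
        # anchor base sits at the same offset after reversal (mirror symmetry)
        flip = strand_aware and strand == "-"
        lo, hi = (pos - flank + 1, pos + flank + 1) if flip else (pos - flank, pos + flank)
        if chrom not in sizes or lo < 0 or hi > sizes[chrom]:
            dropped += 1
            continue
        window = track.values(chrom)[lo:hi]
        binned = window.reshape(n_bins, bin_size).mean(axis=1)
        if flip:
            binned = binned[::-1]
        ids.append(anchor_id)
        rows.append(binned)
    if not rows:
        raise ValueError("no usable anchors (all dropped at chromosome bounds)")
    matrix = np.vstack(rows)
    # canonical reduction order: descending row mean, ties by anchor id
    order = np.lexsort((np.asarray(ids), -matrix.mean(axis=1)))
    return [ids[i] for i in order], matrix[order], dropped


def metagene_profile(
    track: CoverageTrack,
    anchors: SiteSet | list[GeneModel],
    flank: int = 2000,
    bin_size: int = 10,
    strand_aware: bool = True,
    anchor_label: str = "",
) -> MetageneProfile:
    """Average binned coverage over ``[anchor − flank, anchor + flank)``.

    Minus-strand gene windows are reversed when ``strand_aware`` so that
    upstream is always to the left. Anchors whose window exceeds the chromosome
    are dropped and counted in ``n_dropped``; zero usable anchors raise.
    """
    _ids, matrix, dropped = _anchor_rows(track, anchors, flank, bin_size, strand_aware)
    return MetageneProfile(
        values=matrix.mean(axis=0),
        flank=flank,
        bin_size=bin_size,
        n_anchors=matrix.shape[0],
        anchor_label=anchor_label,
        n_dropped=dropped,
    )


def occupancy_heatmap(
    track: CoverageTrack,
    anchors: SiteSet | list[GeneModel],
    flank: int = 2000,
    bin_size: int = 10,
    strand_aware: bool = True,
) -> OccupancyMatrix:
    """Per-anchor occupancy rows, sorted by descending mean occupancy."""
    ids, matrix, dropped = _anchor_rows(track, anchors, flank, bin_size, strand_aware)
    offsets = -flank + bin_size * (np.arange(matrix.shape[1]) + 0.5)
    frame = pd.DataFrame(matrix, index=pd.Index(ids, name="anchor"), columns=offsets)
    return OccupancyMatrix(matrix=frame, flank=flank, bin_size=bin_size, n_dropped=dropped)


def scaled_gene_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    flank: int = 2000,
    flank_bin_size: int = 10,
    body_bins: int = 100,
) -> tuple[np.ndarray, int]:
    """TSS→TES gene-scaled profile: fixed flanks plus body rescaled to bins.

    Each gene contributes ``flank/flank_bin_size`` upstream bins, ``body_bins``
    bins spanning TSS→TES (variable bp per bin), and the same number of
    downstream bins; minus-strand genes are mirrored. Returns the mean profile
    and the number of genes used.
    """
    if flank % flank_bin_size != 0:
        raise ValueError("flank must be a multiple of flank_bin_size")
    n_flank = flank // flank_bin_size
    sizes = track.chrom_sizes
    rows = []
    for g in genes:
        if g.chrom not in sizes:
            continue
        lo, hi = g.start - flank, g.end + flank
        if lo < 0 or hi > sizes[g.chrom] or g.length < body_bins:
            continue
        vals = track.values(g.chrom)
        up = vals[g.start - flank : g.start].reshape(n_flank, flank_bin_size).mean(axis=1)
        down = vals[g.end : g.end + flank].reshape(n_flank, flank_bin_size).mean(axis=1)
        body = np.array([seg.mean() for seg in np.array_split(vals[g.start : g.end], body_bins)])
        row = np.concatenate([up, body, down])
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("no usable genes for scaled profile")
    return np.vstack(rows).mean(axis=0), len(rows)


def normalize_profiles(
    numerator: MetageneProfile,
    denominator: MetageneProfile,
    pseudocount: float = 1e-3,
) -> RatioProfile:
    """Bin-wise ratio of two profiles with a pseudocount in the denominator."""
    if (numerator.flank, numerator.bin_size, numerator.n_bins) != (
        denominator.flank,
        denominator.bin_size,
        denominator.n_bins,
    ):
        raise ValueError("profiles have different binning")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = denominator.values + pseudocount
    if (denom <= 0).any():
        raise ValueError("ratio undefined: denominator + pseudocount not positive everywhere")
    return RatioProfile(
        values=numerator.values / denom,
        flank=numerator.flank,
        bin_size=numerator.bin_size,
        ratio_pseudocount=pseudocount,
    )


def site_density_concordance(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    sites: SiteSet,
    log_pseudocount: float = LOG_DENSITY_PSEUDOCOUNT,
) -> ConcordanceResult:
    """Pearson correlation of two tracks' densities at shared sites.

    Densities are log10-transformed (with a pseudocount) before correlating.
    Zero-variance inputs return a flagged degenerate result (r = nan) rather
    than raising, so batch runs survive.
    """
    if len(sites) < 3:
        raise ValueError("need at least 3 sites for a correlation")
    dens_a = [window_density(track_a, s.chrom, s.start, s.end) for s in sites]
    dens_b = [window_density(track_b, s.chrom, s.start, s.end) for s in sites]
    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "density_a": dens_a,
            "density_b": dens_b,
        }
    )
    log_a = np.log10(np.asarray(dens_a) + log_pseudocount)
    log_b = np.log10(np.asarray(dens_b) + log_pseudocount)
    if np.ptp(log_a) == 0 or np.ptp(log_b) == 0:
        return ConcordanceResult(frame, float("nan"), float("nan"), True, log_pseudocount)
    r, p = stats.pearsonr(log_a, log_b)
    return ConcordanceResult(frame, float(r), float(p), False, log_pseudocount)


def mean_profile_summary(
    profile: MetageneProfile | RatioProfile, bin_range: tuple[int, int] | None = None
) -> float:
    """Mean profile value over a half-open bin range (default: all bins)."""
    values = profile.values
    if bin_range is None:
        bin_range = (0, values.size)
    start, end = bin_range
    if not (0 <= start < end <= values.size):
        raise ValueError(f"bin range [{start}, {end}) outside profile of {values.size} bins")
    return float(values[start:end].mean())
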