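"""Synthetic inputs with known ground truth for the whole pipeline.

Generators emulate the statistical structure the analysis assumes: a toy
chromosome of non-overlapping stranded genes; per-base Poisson ChIP coverage
whose promoter/body mean ratio is a controllable traveling ratio, multiplied in
a chosen gene subset under treatment; negative-binomial RNA-seq counts with
planted down-regulation; TF target sets enriched for the paused genes;
two-dose BH3 depolarization tables constructed to satisfy or violate the
MCL-1-dependence rule; and grayscale images with disk-shaped "nucleoli" of
known pixel areas on Gaussian noise.

Every generator is a pure function of its arguments and a seed: all randomness
flows through a generator derived from ``(seed, stream tag)``, with no global
state, and identical seeds give byte-identical outputs. A truth table
accompanies every stochastic output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genomic import CoverageTrack, GeneModel
from .integration import DepolarizationProfile, GeneSetCollection, classify_mcl1_dependence
from .pausing import TRWindows, tr_windows_for_gene

__all__ = [
    "SimConfig",
    "SizingError",
    "simulate_genome",
    "simulate_rnap2_tracks",
    "simulate_counts",
    "simulate_tf_target_sets",
    "simulate_depolarization",
    "simulate_nucleolus_image",
    "write_counts_tsv",
    "write_image_16bit",
]


class SizingError(ValueError):
    """Requested objects cannot be packed into the available space."""


# distinct stream tags so each generator draws from its own substream of a seed
_STREAM_GENOME = 0
_STREAM_TRACKS = 1
_STREAM_COUNTS = 2
_STREAM_TF = 3
_STREAM_BH3 = 4
_STREAM_IMAGE = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome, ChIP tracks and counts.

    Defaults encode the simulated treatment scenario exercised throughout:
    500 genes on a 10 Mb chromosome, baseline traveling ratios between 2 and 8,
    a 3-fold TR increase in 20% of genes under treatment at a gene-body ChIP
    density of 5 reads/bp, and negative-binomial counts (dispersion 0.1) with a
    2-fold knockdown (log2FC −1) in 20% of genes.
    """

    n_genes: int = 500
    chrom: str = "chrSim"
    chrom_length: int = 10_000_000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    min_gene_spacing: int = 1_000
    promoter_tr_range: tuple[float, float] = (2.0, 8.0)
    frac_affected: float = 0.2
    tr_effect: float = 3.0
    mean_body_density: float = 5.0
    background_density: float = 0.01
    nb_mean_range: tuple[float, float] = (20.0, 2000.0)
    nb_dispersion: float = 0.1
    frac_down: float = 0.2
    lfc_down: float = -1.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        for frac_name in ("frac_affected", "frac_down"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("gene_length_range must be 0 < lo <= hi")
        lo, hi = self.promoter_tr_range
        if not 0 < lo <= hi:
            raise ValueError("promoter_tr_range must be 0 < lo <= hi")
        lo, hi = self.nb_mean_range
        if not 0 < lo <= hi:
            raise ValueError("nb_mean_range must be 0 < lo <= hi")
        if self.tr_effect <= 0 or self.mean_body_density <= 0:
            raise ValueError("tr_effect and mean_body_density must be positive")
        if self.background_density < 0 or self.nb_dispersion < 0:
            raise ValueError("background_density and nb_dispersion must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimConfig) -> list[GeneModel]:
    """Place non-overlapping stranded genes ≥ ``min_gene_spacing`` apart.

    Gene lengths are uniform over ``gene_length_range``; the leftover space is
    distributed among the inter-gene gaps at random, and strands are assigned
    ~50/50. Raises :class:`SizingError` when the requested genes cannot fit.
    """
    n = cfg.n_genes
    if n == 0:
        return []
    if n * (cfg.gene_length_range[1] + cfg.min_gene_spacing) > cfg.chrom_length:
        raise SizingError(
            f"{n} genes of up to {cfg.gene_length_range[1]} bp with {cfg.min_gene_spacing} bp "
            f"spacing do not fit in {cfg.chrom_length} bp"
        )
    rng = _rng(cfg.seed, _STREAM_GENOME)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
    # mandatory space: genes + spacing before each gene and after the last one
    slack = cfg.chrom_length - int(lengths.sum()) - cfg.min_gene_spacing * (n + 1)
    if slack < 0:
        raise SizingError("sampled gene lengths exceed the chromosome; enlarge it")
    extra = np.sort(rng.integers(0, slack + 1, size=n))
    gaps = np.diff(np.concatenate(([0], extra)))
    strands = rng.choice(np.array(["+", "-"]), size=n)
    genes: list[GeneModel] = []
    cursor = cfg.min_gene_spacing
    width = len(str(n))
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        genes.append(GeneModel(cfg.chrom, start, end, f"g{i + 1:0{width}d}", str(strands[i])))
        cursor = end + cfg.min_gene_spacing
    return genes


# ---------------------------------------------------------------------------
# RNAP2 ChIP coverage
# ---------------------------------------------------------------------------


def simulate_rnap2_tracks(
    genes: list[GeneModel],
    cfg: SimConfig,
    windows: TRWindows | None = None,
    affected_genes: set[str] | None = None,
) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame]:
    """Control and treated per-base Poisson coverage plus the per-gene TR truth.

    Each base is drawn independently from Poisson with mean
    ``mean_body_density`` over the gene body and ``TR × mean_body_density``
    over the promoter window (the same strand-aware window the TR estimator
    uses); intergenic background has a fixed low mean. Under treatment the TR
    of exactly ``round(frac_affected × n_genes)`` genes, recorded in the truth
    table, is multiplied by ``tr_effect``. An explicit ``affected_genes`` set
    overrides the random choice (for planted-truth designs).
    """
    windows = windows or TRWindows()
    rng = _rng(cfg.seed, _STREAM_TRACKS)
    n = len(genes)
    trs = rng.uniform(*cfg.promoter_tr_range, size=n)
    if affected_genes is not None:
        unknown = affected_genes - {g.gene_id for g in genes}
        if unknown:
            raise ValueError(f"affected_genes not in the genome: {sorted(unknown)[:5]}")
        affected = np.array([g.gene_id in affected_genes for g in genes])
    else:
        n_affected = round(cfg.frac_affected * n)
        affected_idx = rng.choice(n, size=n_affected, replace=False) if n else np.array([], dtype=int)
        affected = np.zeros(n, dtype=bool)
        affected[affected_idx] = True

    length = cfg.chrom_length
    lam_ctrl = np.full(length, cfg.background_density)
    lam_trt = np.full(length, cfg.background_density)
    for i, gene in enumerate(genes):
        lam_ctrl[gene.start : gene.end] = cfg.mean_body_density
        lam_trt[gene.start : gene.end] = cfg.mean_body_density
        ps, pe, _, _ = tr_windows_for_gene(gene, windows)
        ps, pe = max(ps, 0), min(pe, length)
        lam_ctrl[ps:pe] = trs[i] * cfg.mean_body_density
        eff = cfg.tr_effect if affected[i] else 1.0
        lam_trt[ps:pe] = trs[i] * eff * cfg.mean_body_density
    control = CoverageTrack({cfg.chrom: rng.poisson(lam_ctrl).astype(float)})
    treated = CoverageTrack({cfg.chrom: rng.poisson(lam_trt).astype(float)})
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "tr_control": trs,
            "tr_treated": trs * np.where(affected, cfg.tr_effect, 1.0),
            "affected": affected,
        }
    ).set_index("gene_id")
    return control, treated, truth


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_counts(
    genes: list[GeneModel],
    cfg: SimConfig,
    down_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts (genes × 2·n_replicates) with planted knockdown.

    Gene means are uniform over ``nb_mean_range`` with common dispersion α
    (variance μ + αμ²); ``round(frac_down × n)`` genes have their treated-group
    mean multiplied by ``2^lfc_down``. α = 0 gives the Poisson limit. Columns
    are ``control_1..k, treated_1..k``; the truth table flags the down genes.
    An explicit ``down_genes`` set overrides the random choice.
    """
    if cfg.n_replicates < 2:
        raise ValueError("need n_replicates >= 2 for downstream testing")
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    n = len(genes)
    means = rng.uniform(*cfg.nb_mean_range, size=n)
    if down_genes is not None:
        unknown = down_genes - {g.gene_id for g in genes}
        if unknown:
            raise ValueError(f"down_genes not in the genome: {sorted(unknown)[:5]}")
        down = np.array([g.gene_id in down_genes for g in genes])
    else:
        n_down = round(cfg.frac_down * n)
        down_idx = rng.choice(n, size=n_down, replace=False) if n else np.array([], dtype=int)
        down = np.zeros(n, dtype=bool)
        down[down_idx] = True
    means_trt = means * np.where(down, 2.0 ** cfg.lfc_down, 1.0)

    def draw(mu: np.ndarray, k: int) -> np.ndarray:
        mu_mat = np.repeat(mu[:, None], k, axis=1)
        if cfg.nb_dispersion < 1e-12:
            return rng.poisson(mu_mat)
        size = 1.0 / cfg.nb_dispersion
        p = size / (size + mu_mat)
        return rng.negative_binomial(size, p)

    k = cfg.n_replicates
    mat = np.hstack([draw(means, k), draw(means_trt, k)])
    columns = [f"control_{i + 1}" for i in range(k)] + [f"treated_{i + 1}" for i in range(k)]
    counts = pd.DataFrame(mat, index=pd.Index([g.gene_id for g in genes], name="gene_id"), columns=columns)
    truth = pd.DataFrame(
        {
            "mean_control": means,
            "mean_treated": means_trt,
            "down": down,
        },
        index=counts.index,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# TF target sets
# ---------------------------------------------------------------------------


def simulate_tf_target_sets(
    genes: list[GeneModel],
    paused_truth: set[str],
    n_tfs: int,
    enrichment: float = 10.0,
    seed: int = 0,
    set_size: int | None = None,
    driver_name: str = "TF_driver",
) -> tuple[GeneSetCollection, str]:
    """TF target-set collection with one driver set enriched for paused genes.

    The driver set is sampled without replacement with weight ``enrichment`` on
    paused genes and 1 elsewhere; the remaining ``n_tfs − 1`` sets are uniform.
    ``enrichment = 1`` makes the driver indistinguishable from background in
    expectation. Returns the collection and the driver's set name.
    """
    if n_tfs < 1:
        raise ValueError("need at least one TF set")
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    universe = [g.gene_id for g in genes]
    unknown = paused_truth - set(universe)
    if unknown:
        raise ValueError(f"paused genes not in the gene universe: {sorted(unknown)[:5]}")
    if set_size is None:
        set_size = max(1, len(universe) // 5)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = _rng(seed, _STREAM_TF)
    weights = np.array([enrichment if g in paused_truth else 1.0 for g in universe])
    weights /= weights.sum()
    sets: dict[str, list[str]] = {}
    driver = rng.choice(len(universe), size=set_size, replace=False, p=weights)
    sets[driver_name] = [universe[i] for i in driver]
    width = len(str(max(n_tfs - 1, 1)))
    for j in range(n_tfs - 1):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"TF_{j + 1:0{width}d}"] = [universe[i] for i in idx]
    return GeneSetCollection(sets, universe), driver_name


# ---------------------------------------------------------------------------
# BH3 depolarization tables
# ---------------------------------------------------------------------------


def simulate_depolarization(
    n_lines: int, frac_dependent: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-dose (5/10 µM MS1) depolarization table with known dependence labels.

    Dependent lines are drawn to satisfy the dependence rule (either clearly
    above the 10% threshold, or dose-responsive below it); independent lines
    violate both clauses (≤ 10% at both doses and no increase at the higher
    dose). The classifier therefore round-trips the truth labels exactly.
    """
    if n_lines < 0:
        raise ValueError("n_lines must be non-negative")
    if not 0.0 <= frac_dependent <= 1.0:
        raise ValueError("frac_dependent must be in [0, 1]")
    rng = _rng(seed, _STREAM_BH3)
    n_dep = round(frac_dependent * n_lines)
    rows = []
    labels = []
    width = len(str(max(n_lines, 1)))
    for i in range(n_lines):
        name = f"line{i + 1:0{width}d}"
        if i < n_dep:
            if rng.random() < 0.5:  # exceeds the threshold at the low dose
                low = rng.uniform(10.5, 60.0)
                high = rng.uniform(0.0, low)
            else:  # sub-threshold but dose-responsive
                low = rng.uniform(0.0, 9.5)
                high = low + rng.uniform(0.5, 15.0)
            labels.append("dependent")
        else:
            low = rng.uniform(0.0, 10.0)
            high = rng.uniform(0.0, low) if low > 0 else 0.0
            labels.append("independent")
        rows.append((name, low, high))
    table = pd.DataFrame(rows, columns=["line", "depol_5uM", "depol_10uM"]).set_index("line")
    truth = pd.Series(labels, index=table.index, name="dependence")
    # internal consistency: the rule must reproduce the labels by construction
    for name, row in table.iterrows():
        prof = DepolarizationProfile(name, row["depol_5uM"], row["depol_10uM"])
        assert classify_mcl1_dependence(prof) == truth[name]
    return table, truth


# ---------------------------------------------------------------------------
# Nucleolus images
# ---------------------------------------------------------------------------


def _disk_offsets(area: int) -> np.ndarray:
    """Offsets of the ``area`` pixels nearest the origin — a digital disk."""
    r = int(np.ceil(np.sqrt(area / np.pi))) + 2
    grid = np.arange(-r, r + 1)
    rr, cc = np.meshgrid(grid, grid, indexing="ij")
    d2 = rr**2 + cc**2
    # stable lexicographic tie-break keeps the shape deterministic
    order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    return np.column_stack((rr.ravel()[order][:area], cc.ravel()[order][:area]))


def simulate_nucleolus_image(
    disk_areas: list[int],
    image_size: tuple[int, int] = (128, 128),
    background_sd: float = 0.1,
    seed: int = 0,
    foreground: float = 1.0,
    margin: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Bright disks of exact pixel areas on a Gaussian-noise background.

    Disks are digital disks (the ``area`` nearest pixels to a center), placed
    uniformly at random without overlap and with ``margin`` px of clearance so
    components stay separable; impossible placements raise
    :class:`SizingError`. Returns ``(image, truth labels)`` where disk i
    (1-based label) has exactly ``disk_areas[i-1]`` pixels.
    """
    h, w = image_size
    rng = _rng(seed, _STREAM_IMAGE)
    image = rng.normal(0.0, background_sd, size=(h, w))
    truth = np.zeros((h, w), dtype=int)
    occupied = np.zeros((h, w), dtype=bool)
    for lab, area in enumerate(disk_areas, start=1):
        if area < 1:
            raise ValueError("disk areas must be positive")
        offsets = _disk_offsets(int(area))
        r_ext = int(np.abs(offsets).max())
        if 2 * (r_ext + margin) + 1 > min(h, w):
            raise SizingError(f"disk of area {area} cannot fit in a {h}x{w} image")
        placed = False
        for _ in range(2000):
            cr = int(rng.integers(r_ext + margin, h - r_ext - margin))
            cc = int(rng.integers(r_ext + margin, w - r_ext - margin))
            rows = offsets[:, 0] + cr
            cols = offsets[:, 1] + cc
            lo_r, hi_r = rows.min() - margin, rows.max() + margin + 1
            lo_c, hi_c = cols.min() - margin, cols.max() + margin + 1
            if occupied[lo_r:hi_r, lo_c:hi_c].any():
                continue
            truth[rows, cols] = lab
            occupied[lo_r:hi_r, lo_c:hi_c] = True
            image[rows, cols] += foreground
            placed = True
            break
        if not placed:
            raise SizingError(
                f"could not place disk {lab} (area {area}) without overlap; "
                "reduce areas or enlarge the image"
            )
    return image, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", float_format="%.10g")


def write_image_16bit(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a float image as 16-bit grayscale TIFF (PNG by extension)."""
    lo, hi = float(image.min()), float(image.max())
    scale = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    data = (scale * 65535).astype(np.uint16)
    path = os.fspath(path)
    if path.lower().endswith(".png"):
        import imageio.v3 as iio

        iio.imwrite(path, data)
    else:
        import tifffile

        tifffile.imwrite(path, data)
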