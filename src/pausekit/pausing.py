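"""Traveling-ratio (pausing-index) statistics for RNAP2 ChIP-seq.

The traveling ratio (TR) of a gene is the ratio of RNAP2 density in a
promoter-proximal window to the density over the gene body; promoter-proximal
pausing raises it, and pause release (e.g. by CDK9) lowers it. This module
computes per-gene TRs from a coverage track, compares TR distributions between
conditions with a two-sample KS test on log TR, and calls genes with increased
pausing by a TR fold-change rule.

The promoter/body windows follow the convention common in the pausing
literature — promoter [TSS−30, TSS+300), body [TSS+300, TES) in transcription
direction — and every bound is a parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .genomic import CoverageTrack, GeneModel

__all__ = [
    "TRWindows",
    "TravelingRatioTable",
    "PausingCallSet",
    "tr_windows_for_gene",
    "compute_traveling_ratios",
    "tr_ecdf",
    "tr_shift_test",
    "call_paused_genes",
    "write_pausing_tsv",
    "read_pausing_tsv",
]


@dataclass(frozen=True)
class TRWindows:
    """Window geometry and filters for traveling-ratio computation.

    All distances are bp along the direction of transcription. ``body_pseudocount``
    (reads/bp) is added to the body density in the TR denominator only, so a
    zero-coverage body does not blow up the ratio; ``min_body_density`` flags
    genes whose body coverage is too low for the TR to be trusted.
    """

    promoter_upstream: int = 30
    promoter_downstream: int = 300
    body_start_offset: int = 300
    min_gene_length: int = 1000
    body_pseudocount: float = 1e-3
    min_body_density: float = 0.01

    def __post_init__(self) -> None:
        for name in ("promoter_upstream", "promoter_downstream", "body_start_offset", "min_gene_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.body_pseudocount < 0 or self.min_body_density < 0:
            raise ValueError("pseudocount and coverage floor must be non-negative")
        if self.body_start_offset < self.promoter_downstream:
            warnings.warn(
                "body_start_offset < promoter_downstream: promoter and body windows overlap",
                stacklevel=2,
            )


@dataclass
class TravelingRatioTable:
    """Per-gene promoter/body densities and TRs for one condition.

    ``table`` is indexed by gene_id with columns ``promoter_density``,
    ``body_density``, ``tr`` and ``low_coverage``; ``excluded`` maps each
    excluded gene_id to the reason (short gene, window off chromosome).
    """

    table: pd.DataFrame
    condition: str
    windows: TRWindows
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def usable(self) -> pd.DataFrame:
        """Rows passing the body-coverage filter."""
        return self.table[~self.table["low_coverage"]]


@dataclass
class PausingCallSet:
    """Per-gene TR fold change and the increased-pausing calls.

    A gene is called paused only when it passes the coverage filter in both
    conditions and its TR fold (treated/control) reaches ``min_fold``.
    """

    table: pd.DataFrame
    min_fold: float
    summary: dict[str, float]

    @property
    def paused_genes(self) -> set[str]:
        return set(self.table.index[self.table["paused"]])

    @property
    def tested_genes(self) -> set[str]:
        return set(self.table.index)


def tr_windows_for_gene(gene: GeneModel, windows: TRWindows) -> tuple[int, int, int, int]:
    """Genomic (start, end) pairs of the promoter and body windows of a gene.

    Returns ``(prom_start, prom_end, body_start, body_end)`` in 0-based
    half-open genome coordinates; on the − strand the windows are mirrored so
    that offsets are measured along the direction of transcription.
    """
    if gene.strand == "+":
        prom = (gene.tss - windows.promoter_upstream, gene.tss + windows.promoter_downstream)
        body = (gene.tss + windows.body_start_offset, gene.tes)
    else:
        prom = (gene.tss - windows.promoter_downstream + 1, gene.tss + windows.promoter_upstream + 1)
        body = (gene.tes + 1, gene.tss - windows.body_start_offset + 1)
    return prom[0], prom[1], body[0], body[1]


def compute_traveling_ratios(
    track: CoverageTrack,
    genes: list[GeneModel],
    windows: TRWindows | None = None,
    condition: str = "",
) -> TravelingRatioTable:
    """Compute per-gene traveling ratios from a (normalized) coverage track.

    Genes shorter than ``windows.min_gene_length``, or whose promoter/body
    window falls outside the chromosome, are excluded and reported in
    ``excluded`` rather than raising.
    """
    windows = windows or TRWindows()
    sizes = track.chrom_sizes
    rows: list[tuple[str, float, float, float, bool]] = []
    excluded: dict[str, str] = {}
    for gene in genes:
        if gene.chrom not in sizes:
            excluded[gene.gene_id] = "unknown_chromosome"
            continue
        if gene.length < windows.min_gene_length:
            excluded[gene.gene_id] = "short_gene"
            continue
        ps, pe, bs, be = tr_windows_for_gene(gene, windows)
        if bs >= be:
            excluded[gene.gene_id] = "degenerate_body"
            continue
        size = sizes[gene.chrom]
        if ps < 0 or pe > size or bs < 0 or be > size:
            excluded[gene.gene_id] = "window_outside_chromosome"
            continue
        vals = track.values(gene.chrom)
        prom_density = float(vals[ps:pe].sum() / (pe - ps))
        body_density = float(vals[bs:be].sum() / (be - bs))
        tr = prom_density / (body_density + windows.body_pseudocount)
        rows.append(
            (gene.gene_id, prom_density, body_density, tr, body_density < windows.min_body_density)
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "promoter_density", "body_density", "tr", "low_coverage"]
    ).set_index("gene_id")
    return TravelingRatioTable(table=table, condition=condition, windows=windows, excluded=excluded)


def tr_ecdf(table: TravelingRatioTable) -> ECDF:
    """Empirical CDF over log10 TR of genes passing the coverage filter."""
    usable = table.usable()
    if usable.empty:
        raise ValueError("no genes pass the coverage filter")
    tr = usable["tr"].to_numpy()
    if (tr <= 0).any():
        raise ValueError("non-positive TR encountered")
    return ECDF(np.log10(tr))


def _paired_log_tr(
    control: TravelingRatioTable, treated: TravelingRatioTable
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    common = control.usable().index.intersection(treated.usable().index)
    if len(common) == 0:
        raise ValueError("control and treated share no genes after coverage filtering")
    return (
        np.log(control.table.loc[common, "tr"].to_numpy()),
        np.log(treated.table.loc[common, "tr"].to_numpy()),
        common,
    )


def tr_shift_test(
    control: TravelingRatioTable, treated: TravelingRatioTable
) -> tuple[float, float]:
    """Two-sample KS test on log TR over the shared coverage-filtered genes.

    Returns ``(D, p)``. A global right-shift of the treated distribution (more
    pausing) shows up as a large D with treated ECDF below control. Note the
    per-gene pairing: when baseline TRs vary strongly between genes the two
    samples are positively dependent and the test is conservative.
    """
    log_ctrl, log_trt, _ = _paired_log_tr(control, treated)
    res = stats.ks_2samp(log_ctrl, log_trt)
    return float(res.statistic), float(res.pvalue)


def call_paused_genes(
    control: TravelingRatioTable,
    treated: TravelingRatioTable,
    min_fold: float = 1.5,
) -> PausingCallSet:
    """Call genes with increased pausing by TR fold change treated/control.

    The tested universe is the intersection of the two gene universes (genes
    excluded by neither condition); genes must additionally pass the coverage
    filter in both conditions to be called. Disjoint universes raise.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    common = control.table.index.intersection(treated.table.index)
    if len(common) == 0:
        raise ValueError("control and treated gene universes do not intersect")
    tr_c = control.table.loc[common, "tr"]
    tr_t = treated.table.loc[common, "tr"]
    low_c = control.table.loc[common, "low_coverage"]
    low_t = treated.table.loc[common, "low_coverage"]
    fold = tr_t / tr_c
    covered = ~(low_c | low_t)
    paused = covered & (fold >= min_fold)
    table = pd.DataFrame(
        {
            "tr_control": tr_c,
            "tr_treated": tr_t,
            "tr_fold": fold,
            "low_coverage_either": ~covered,
            "paused": paused,
        }
    )
    n_tested = int(covered.sum())
    n_paused = int(paused.sum())
    summary = {
        "n_genes": int(len(common)),
        "n_tested": n_tested,
        "n_paused": n_paused,
        "fraction_paused": n_paused / n_tested if n_tested else float("nan"),
        "min_fold": float(min_fold),
    }
    return PausingCallSet(table=table, min_fold=float(min_fold), summary=summary)


def write_pausing_tsv(
    control: TravelingRatioTable,
    treated: TravelingRatioTable,
    calls: PausingCallSet,
    path,
) -> None:
    """Write the merged per-gene TR/pausing table the CLI exposes."""
    common = calls.table.index
    out = pd.DataFrame(
        {
            "promoter_density_ctrl": control.table.loc[common, "promoter_density"],
            "promoter_density_trt": treated.table.loc[common, "promoter_density"],
            "body_density_ctrl": control.table.loc[common, "body_density"],
            "body_density_trt": treated.table.loc[common, "body_density"],
            "tr_ctrl": calls.table["tr_control"],
            "tr_trt": calls.table["tr_treated"],
            "tr_fold": calls.table["tr_fold"],
            "low_coverage": calls.table["low_coverage_either"],
            "paused": calls.table["paused"],
        }
    )
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_pausing_tsv(path) -> PausingCallSet:
    """Rebuild a :class:`PausingCallSet` from a TSV written by the CLI."""
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    table = pd.DataFrame(
        {
            "tr_control": frame["tr_ctrl"],
            "tr_treated": frame["tr_trt"],
            "tr_fold": frame["tr_fold"],
            "low_coverage_either": frame["low_coverage"].astype(bool),
            "paused": frame["paused"].astype(bool),
        }
    )
    covered = ~table["low_coverage_either"]
    n_tested = int(covered.sum())
    n_paused = int(table["paused"].sum())
    summary = {
        "n_genes": int(len(table)),
        "n_tested": n_tested,
        "n_paused": n_paused,
        "fraction_paused": n_paused / n_tested if n_tested else float("nan"),
        "min_fold": float("nan"),
    }
    return PausingCallSet(table=table, min_fold=float("nan"), summary=summary)
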