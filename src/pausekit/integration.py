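"""ChIP-seq/RNA-seq integration, enrichment and phenotyping statistics.

Covers: a transparent differential-expression test (CPM → log2(CPM+1) → Welch t
→ Benjamini–Hochberg), intersection of paused and down-regulated genes
(CDK9-dependent gene calling), Fisher odds-ratio enrichment of a query set
against TF-target collections, set-overlap summaries, a rank-based
single-sample gene-set score with Pearson correlation against expression of a
marker gene, ΔΔCt relative quantification, the 18S/47S rRNA processing ratio,
and the two-dose BH3-profiling rule for MCL-1 dependence.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pausing import PausingCallSet

__all__ = [
    "GeneSetCollection",
    "DifferentialTable",
    "DepolarizationProfile",
    "OverlapSummary",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "differential_expression",
    "call_cdk9_dependent",
    "tf_overlap_enrichment",
    "set_overlap_summary",
    "single_sample_score",
    "score_expression_correlation",
    "relative_quant",
    "processing_ratio",
    "classify_mcl1_dependence",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a common universe.

    Sets are intersected with the universe on construction (harmonization), so
    every stored set is a subset of it.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        uni = frozenset(universe)
        harmonized = {name: frozenset(members) & uni for name, members in sets.items()}
        if len(harmonized) != len(sets):
            raise ValueError("gene-set names must be unique")
        object.__setattr__(self, "sets", harmonized)
        object.__setattr__(self, "universe", uni)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | os.PathLike, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read GMT-like text (name, tab, description, tab, gene ids).

    If no universe is given, the union of all set members is used.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT record needs name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, universe)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# Differential expression and CDK9-dependent gene calling
# ---------------------------------------------------------------------------


@dataclass
class DifferentialTable:
    """Per-gene differential-expression results (treated vs control).

    ``table`` is indexed by gene_id with columns ``log2fc``, ``t``, ``p``,
    ``q``; thresholds used for calling a gene "down" travel with the table.
    """

    table: pd.DataFrame
    lfc_threshold: float = -0.585
    q_threshold: float = 0.05
    excluded_zero: list[str] = field(default_factory=list)

    def down_genes(self) -> set[str]:
        t = self.table
        return set(t.index[(t["log2fc"] <= self.lfc_threshold) & (t["q"] <= self.q_threshold)])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: pd.DataFrame,
    groups: Sequence[str],
    control: str = "control",
    treated: str = "treated",
    lfc_threshold: float = -0.585,
    q_threshold: float = 0.05,
) -> DifferentialTable:
    """Welch t-test on log2(CPM + 1) per gene, BH-adjusted across genes.

    ``counts`` is genes × samples; ``groups`` labels each column as control or
    treated (≥ 2 replicates each). Genes with zero counts in every sample are
    excluded from testing and reported in ``excluded_zero``. log2FC is the mean
    log2(CPM+1) difference, treated minus control.
    """
    groups = list(groups)
    if len(groups) != counts.shape[1]:
        raise ValueError("one group label per counts column is required")
    labels = set(groups)
    if not {control, treated} <= labels or labels - {control, treated}:
        raise ValueError(f"groups must use labels {control!r}/{treated!r}, got {sorted(labels)}")
    mask_c = np.array([g == control for g in groups])
    mask_t = ~mask_c
    if mask_c.sum() < 2 or mask_t.sum() < 2:
        raise ValueError("need at least 2 replicates per group")

    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    zero = mat.sum(axis=1) == 0
    excluded = list(counts.index[zero])
    kept = counts.index[~zero]
    mat = mat[~zero]

    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("a sample has zero total counts")
    logcpm = np.log2(mat / lib * 1e6 + 1.0)
    a, b = logcpm[:, mask_t], logcpm[:, mask_c]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trip a scipy precision warning; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # identical constant groups: no evidence of change, not a failure
    degenerate = ~np.isfinite(p)
    t[degenerate & (log2fc == 0)] = 0.0
    p[degenerate] = 1.0
    q = bh_adjust(p)
    table = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p, "q": q}, index=kept)
    table.index.name = "gene_id"
    return DifferentialTable(table, lfc_threshold, q_threshold, excluded)


def call_cdk9_dependent(
    paused: PausingCallSet, de: DifferentialTable
) -> tuple[set[str], dict[str, int]]:
    """Genes both paused (increased TR) and transcriptionally down-regulated."""
    paused_genes = paused.paused_genes
    down = de.down_genes()
    dependent = paused_genes & down
    summary = {
        "n_paused": len(paused_genes),
        "n_down": len(down),
        "n_intersection": len(dependent),
    }
    return dependent, summary


# ---------------------------------------------------------------------------
# Gene-set enrichment and overlap
# ---------------------------------------------------------------------------


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc, Haldane–Anscombe corrected if any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def tf_overlap_enrichment(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Fisher-exact enrichment of a query gene set against each TF-target set.

    For each set the 2×2 table over the universe is (a = query ∩ set,
    b = query ∖ set, c = set ∖ query, d = neither). Returns one row per TF,
    sorted by descending odds ratio then ascending p; q is BH across TFs.
    The Fisher p is computed on the uncorrected table; only the reported odds
    ratio uses the Haldane correction when a cell is empty.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= collection.universe:
        missing = sorted(query - collection.universe)[:5]
        raise ValueError(f"query is not a subset of the universe (e.g. {missing})")
    n_universe = len(collection.universe)
    rows = []
    for name in collection.names():
        members = collection[name]
        if not members:
            raise ValueError(f"TF set {name!r} is empty after harmonization")
        a = len(query & members)
        b = len(query) - a
        c = len(members) - a
        d = n_universe - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, b, c, d, _odds_ratio(a, b, c, d), float(p)))
    frame = pd.DataFrame(rows, columns=["tf", "a", "b", "c", "d", "odds_ratio", "p"])
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame = frame.sort_values(
        ["odds_ratio", "p", "tf"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_intersection: int
    fraction_of_a: float
    fraction_of_b: float


def set_overlap_summary(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapSummary:
    """Exact intersection counts and overlap fractions of two gene sets."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_intersection=inter,
        fraction_of_a=inter / len(a) if a else float("nan"),
        fraction_of_b=inter / len(b) if b else float("nan"),
    )


# ---------------------------------------------------------------------------
# Single-sample gene-set scoring
# ---------------------------------------------------------------------------


def single_sample_score(
    expression: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 0.25,
) -> float:
    """Rank-based single-sample enrichment score of a gene set.

    Genes are ranked by descending expression (ties broken by gene id). Each
    gene carries a weight |centered rank|^``weight_exponent``; the score is the
    mean of the weighted Kolmogorov running sum (in-set CDF minus out-of-set
    CDF) over all rank positions. Using ranks only makes the score invariant
    under any strictly monotone transform of the expression values, and the
    symmetric weights make it exactly antisymmetric under rank reversal.
    Positive scores mean the set concentrates at the top of the ranking.
    """
    expr = pd.Series(expression, dtype=float)
    if expr.empty:
        raise ValueError("no expression values")
    members = set(gene_set) & set(expr.index)
    if not members:
        raise ValueError("gene set does not intersect the measured genes")
    n = len(expr)
    m = len(members)
    if m == n:
        raise ValueError("gene set covers every measured gene; score undefined")
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    hit = np.array([g in members for g in order])
    centered = (n + 1) / 2.0 - np.arange(1, n + 1)
    weights = np.abs(centered) ** weight_exponent
    hit_w = np.where(hit, weights, 0.0)
    p_hit = np.cumsum(hit_w) / hit_w.sum()
    p_miss = np.cumsum(~hit) / (n - m)
    return float(np.sum(p_hit - p_miss) / n)


def score_expression_correlation(
    scores: Sequence[float], expr: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (two-tailed p) between per-sample scores and gene expression."""
    s = np.asarray(scores, dtype=float)
    e = np.asarray(expr, dtype=float)
    if s.shape != e.shape or s.size < 3:
        raise ValueError("need >= 3 paired samples")
    if not (np.isfinite(s).all() and np.isfinite(e).all()):
        raise ValueError("inputs must be finite")
    r, p = stats.pearsonr(s, e)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# qPCR relative quantification and BH3 dependence rule
# ---------------------------------------------------------------------------


def relative_quant(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Fold change by the ΔΔCt method: 2^−[(Ct_t − Ct_ref)_trt − (Ct_t − Ct_ref)_ctrl]."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def processing_ratio(expr_18s: float, expr_47s: float) -> float:
    """rRNA processing efficiency proxy: mature 18S over 47S pre-rRNA."""
    if expr_47s == 0:
        raise ZeroDivisionError("47S expression is zero; processing ratio undefined")
    return float(expr_18s / expr_47s)


@dataclass(frozen=True)
class DepolarizationProfile:
    """Mitochondrial depolarization (%) of one line at two MS1 doses."""

    line: str
    depol_at_low: float
    depol_at_high: float

    def __post_init__(self) -> None:
        for v in (self.depol_at_low, self.depol_at_high):
            if not -100.0 <= v <= 100.0:
                raise ValueError(f"{self.line}: depolarization {v}% outside [-100, 100]")


def classify_mcl1_dependence(profile: DepolarizationProfile, threshold: float = 10.0) -> str:
    """Two-dose BH3-profiling rule for MCL-1 dependence.

    A line is MCL-1 dependent if its depolarization exceeds the threshold at
    either dose, or if depolarization is higher at the higher MS1 dose;
    otherwise independent.
    """
    exceeds = max(profile.depol_at_low, profile.depol_at_high) > threshold
    dose_responsive = profile.depol_at_high > profile.depol_at_low
    return "dependent" if (exceeds or dose_responsive) else "independent"
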