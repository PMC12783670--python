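"""DE, enrichment, set scoring, ΔΔCt, and the BH3 dependence rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from pausekit import (
    DepolarizationProfile,
    GeneSetCollection,
    SimConfig,
    bh_adjust,
    call_cdk9_dependent,
    classify_mcl1_dependence,
    differential_expression,
    processing_ratio,
    read_gmt,
    relative_quant,
    score_expression_correlation,
    set_overlap_summary,
    simulate_counts,
    simulate_genome,
    simulate_tf_target_sets,
    single_sample_score,
    tf_overlap_enrichment,
    write_gmt,
)
from pausekit.integration import DifferentialTable
from pausekit.pausing import PausingCallSet


def brute_force_bh(p):
    """Step-up definition computed directly from first principles."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, total = a + b, a + c, a + b + c + d
    rv = hypergeom(total, row1, col1)
    support = np.arange(max(0, row1 + col1 - total), min(row1, col1) + 1)
    probs = rv.pmf(support)
    cutoff = rv.pmf(a) * (1 + 1e-7)
    return float(probs[probs <= cutoff].sum())


class TestDifferentialExpression:
    def test_identical_groups_give_zero_lfc(self):
        counts = pd.DataFrame(
            {"control_1": [10, 50], "control_2": [12, 48], "treated_1": [10, 50], "treated_2": [12, 48]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        de = differential_expression(counts, ["control", "control", "treated", "treated"])
        assert np.allclose(de.table["log2fc"], 0.0)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"control_1": [10], "treated_1": [10]}, index=["g1"])
        with pytest.raises(ValueError, match="2 replicates"):
            differential_expression(counts, ["control", "treated"])

    def test_all_zero_genes_excluded_and_reported(self):
        counts = pd.DataFrame(
            {"control_1": [0, 5], "control_2": [0, 7], "treated_1": [0, 6], "treated_2": [0, 4]},
            index=pd.Index(["dead", "live"], name="gene_id"),
        )
        de = differential_expression(counts, ["control", "control", "treated", "treated"])
        assert de.excluded_zero == ["dead"]
        assert list(de.table.index) == ["live"]

    def test_planted_knockdown_recovered(self):
        """Median estimated log2FC of planted −1 genes lands in [−1.3, −0.7]."""
        cfg = SimConfig(
            n_genes=500, chrom_length=10_000_000, gene_length_range=(2000, 3000),
            frac_down=0.2, lfc_down=-1.0, n_replicates=5, seed=31,
        )
        genes = simulate_genome(cfg)
        counts, truth = simulate_counts(genes, cfg)
        de = differential_expression(counts, ["control"] * 5 + ["treated"] * 5)
        planted = truth.index[truth["down"]]
        med = de.table.loc[planted, "log2fc"].median()
        assert -1.3 <= med <= -0.7

    def test_down_calls_enrich_for_planted_truth(self):
        cfg = SimConfig(
            n_genes=400, chrom_length=10_000_000, gene_length_range=(2000, 3000),
            frac_down=0.25, lfc_down=-2.0, n_replicates=5, seed=13,
        )
        genes = simulate_genome(cfg)
        counts, truth = simulate_counts(genes, cfg)
        de = differential_expression(counts, ["control"] * 5 + ["treated"] * 5)
        down = de.down_genes()
        planted = set(truth.index[truth["down"]])
        assert len(down & planted) / len(planted) > 0.9
        assert len(down - planted) / (len(truth) - len(planted)) < 0.05


class TestBH:
    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_step_up_property(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrichment:
    @staticmethod
    def collection(sets, universe):
        return GeneSetCollection(sets, universe)

    def test_balanced_table_gives_or_one(self):
        universe = [f"g{i}" for i in range(40)]
        query = set(universe[:20])
        tf_set = set(universe[:10]) | set(universe[20:30])  # a=b=c=d=10
        rows = tf_overlap_enrichment(query, self.collection({"tf": tf_set}, universe))
        assert rows.loc[0, "odds_ratio"] == pytest.approx(1.0)

    def test_or_16_and_p_match_enumeration(self):
        universe = [f"g{i}" for i in range(50)]
        query = set(universe[:25])
        tf_set = set(universe[:20]) | set(universe[25:30])  # a=20 b=5 c=5 d=20
        rows = tf_overlap_enrichment(query, self.collection({"tf": tf_set}, universe))
        assert rows.loc[0, ["a", "b", "c", "d"]].tolist() == [20, 5, 5, 20]
        assert rows.loc[0, "odds_ratio"] == pytest.approx(16.0)
        assert rows.loc[0, "p"] == pytest.approx(fisher_two_sided_enumeration(20, 5, 5, 20), rel=1e-9)

    def test_haldane_correction_only_on_zero_cells(self):
        universe = [f"g{i}" for i in range(20)]
        query = set(universe[:10])
        tf_set = set(universe[:5])  # c = 0
        rows = tf_overlap_enrichment(query, self.collection({"tf": tf_set}, universe))
        assert rows.loc[0, "odds_ratio"] == pytest.approx((5.5 * 10.5) / (5.5 * 0.5))

    def test_sorted_by_or_then_p(self):
        universe = [f"g{i}" for i in range(60)]
        query = set(universe[:30])
        sets = {
            "strong": set(universe[:20]) | set(universe[30:35]),
            "weak": set(universe[:15]) | set(universe[30:45]),
            "null": set(universe[15:30]) | set(universe[45:60]),
        }
        rows = tf_overlap_enrichment(query, self.collection(sets, universe))
        assert list(rows["odds_ratio"]) == sorted(rows["odds_ratio"], reverse=True)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tf_overlap_enrichment(set(), self.collection({"tf": {"g1"}}, ["g1", "g2"]))

    def test_driver_tf_usually_ranks_first(self):
        """Planted driver (10× sampling weight) tops the OR ranking."""
        cfg = SimConfig(n_genes=500, chrom_length=10_000_000, gene_length_range=(2000, 3000), seed=17)
        genes = simulate_genome(cfg)
        paused = {g.gene_id for g in genes[:100]}
        first = 0
        for seed in range(100):
            collection, driver = simulate_tf_target_sets(genes, paused, n_tfs=20, enrichment=10.0, seed=seed)
            rows = tf_overlap_enrichment(paused, collection)
            first += rows.loc[0, "tf"] == driver
        assert first >= 90


class TestSetOps:
    def test_worked_overlap(self):
        ov = set_overlap_summary({str(i) for i in range(1, 11)}, {str(i) for i in range(6, 16)})
        assert (ov.n_intersection, ov.fraction_of_a) == (5, 0.5)

    def test_identical_sets(self):
        ov = set_overlap_summary({"a", "b"}, {"a", "b"})
        assert ov.fraction_of_a == 1.0 and ov.fraction_of_b == 1.0

    def test_random_sets_match_brute_force(self, rng):
        pool = [f"g{i}" for i in range(200)]
        a = set(rng.choice(pool, 80, replace=False))
        b = set(rng.choice(pool, 50, replace=False))
        ov = set_overlap_summary(a, b)
        inter = len([x for x in a if x in b])
        assert ov.n_intersection == inter
        assert ov.fraction_of_b == pytest.approx(inter / 50)

    def test_cdk9_dependent_is_intersection(self):
        table = pd.DataFrame(
            {
                "tr_control": [2.0, 2.0, 2.0],
                "tr_treated": [6.0, 6.0, 2.0],
                "tr_fold": [3.0, 3.0, 1.0],
                "low_coverage_either": [False] * 3,
                "paused": [True, True, False],
            },
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        calls = PausingCallSet(table, 1.5, {})
        de_frame = pd.DataFrame(
            {"log2fc": [-1.0, 0.0, -1.0], "t": [0, 0, 0], "p": [0.001, 0.9, 0.001], "q": [0.01, 0.9, 0.01]},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        de = DifferentialTable(de_frame)
        dependent, summary = call_cdk9_dependent(calls, de)
        assert dependent == {"a"}
        assert summary == {"n_paused": 2, "n_down": 2, "n_intersection": 1}

    def test_paused_subset_of_down_returns_paused(self):
        table = pd.DataFrame(
            {
                "tr_control": [2.0],
                "tr_treated": [6.0],
                "tr_fold": [3.0],
                "low_coverage_either": [False],
                "paused": [True],
            },
            index=pd.Index(["a"], name="gene_id"),
        )
        de_frame = pd.DataFrame(
            {"log2fc": [-2.0, -2.0], "t": [0, 0], "p": [1e-5, 1e-5], "q": [1e-4, 1e-4]},
            index=pd.Index(["a", "z"], name="gene_id"),
        )
        dependent, _ = call_cdk9_dependent(PausingCallSet(table, 1.5, {}), DifferentialTable(de_frame))
        assert dependent == {"a"}

    def test_planted_core_recovered_by_integration(self):
        """A 50-gene core both paused and knocked down is nearly fully recovered."""
        from pausekit import call_paused_genes, compute_traveling_ratios, simulate_rnap2_tracks

        cfg = SimConfig(
            n_genes=500, chrom_length=10_000_000, gene_length_range=(5000, 8000),
            tr_effect=3.0, mean_body_density=5.0, lfc_down=-2.0, n_replicates=5, seed=23,
        )
        genes = simulate_genome(cfg)
        ids = [g.gene_id for g in genes]
        core = set(ids[:50])
        affected = core | set(ids[50:100])
        down = core | set(ids[100:150])
        control, treated, _ = simulate_rnap2_tracks(genes, cfg, affected_genes=affected)
        counts, _ = simulate_counts(genes, cfg, down_genes=down)
        calls = call_paused_genes(
            compute_traveling_ratios(control, genes), compute_traveling_ratios(treated, genes)
        )
        de = differential_expression(counts, ["control"] * 5 + ["treated"] * 5)
        dependent, _ = call_cdk9_dependent(calls, de)
        assert len(dependent & core) >= 45  # >= 90% of the planted core
        assert len(dependent - (affected & down)) == 0

    def test_gmt_round_trip(self, tmp_path):
        collection = GeneSetCollection({"s1": {"a", "b"}, "s2": {"c"}}, ["a", "b", "c", "d"])
        path = tmp_path / "sets.gmt"
        write_gmt(collection, path)
        back = read_gmt(path, universe=["a", "b", "c", "d"])
        assert back.sets == collection.sets


class TestSingleSampleScore:
    @staticmethod
    def expression(n, rng):
        return pd.Series(rng.normal(size=n), index=[f"g{i:04d}" for i in range(n)])

    def test_top_set_is_extremal(self, rng):
        expr = self.expression(300, rng)
        top = set(expr.sort_values(ascending=False).index[:40])
        top_score = single_sample_score(expr, top)
        for _ in range(200):
            other = set(rng.choice(expr.index, 40, replace=False))
            assert single_sample_score(expr, other) <= top_score + 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        expr = pd.Series(rng.uniform(0.1, 5.0, 200), index=[f"g{i}" for i in range(200)])
        gene_set = set(rng.choice(expr.index, 30, replace=False))
        assert single_sample_score(expr, gene_set) == pytest.approx(
            single_sample_score(expr**3, gene_set), abs=1e-12
        )

    def test_random_sets_center_on_zero(self, rng):
        expr = self.expression(1000, rng)
        scores = np.array(
            [
                single_sample_score(expr, set(rng.choice(expr.index, 50, replace=False)))
                for _ in range(2000)
            ]
        )
        se = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean()) < 3 * se

    def test_antisymmetric_under_rank_reversal(self, rng):
        expr = self.expression(201, rng)
        gene_set = set(rng.choice(expr.index, 30, replace=False))
        assert single_sample_score(-expr, gene_set) == pytest.approx(
            -single_sample_score(expr, gene_set), abs=1e-10
        )

    def test_disjoint_set_rejected(self, rng):
        expr = self.expression(50, rng)
        with pytest.raises(ValueError, match="intersect"):
            single_sample_score(expr, {"absent"})


class TestCorrelationAndQpcr:
    def test_perfect_correlations(self):
        s = [0.1, 0.5, 0.9, 1.3]
        assert score_expression_correlation(s, s)[0] == pytest.approx(1.0)
        assert score_expression_correlation(s, [-x for x in s])[0] == pytest.approx(-1.0)

    def test_ten_point_closed_form(self, rng):
        s = rng.normal(size=10)
        e = 0.6 * s + rng.normal(scale=0.3, size=10)
        r, p = score_expression_correlation(s, e)
        sx, sy = s - s.mean(), e - e.mean()
        expected_r = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        assert r == pytest.approx(expected_r, rel=1e-12)
        from scipy.stats import t as tdist

        tt = expected_r * np.sqrt(8 / (1 - expected_r**2))
        assert p == pytest.approx(2 * tdist.sf(abs(tt), 8), rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            score_expression_correlation([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("ddct,fold", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_ddct_fold_change(self, ddct, fold):
        assert relative_quant(10 + ddct, 10, 10, 10) == pytest.approx(fold)

    def test_processing_ratio(self):
        assert processing_ratio(3.0, 2.0) == pytest.approx(1.5)
        with pytest.raises(ZeroDivisionError):
            processing_ratio(1.0, 0.0)


class TestMcl1Rule:
    @pytest.mark.parametrize(
        "low,high,expected",
        [
            (12.0, 9.0, "dependent"),  # exceeds 10% at the low dose
            (4.0, 8.0, "dependent"),  # higher at the higher dose
            (8.0, 6.0, "independent"),  # neither clause
        ],
    )
    def test_rule_on_reference_cases(self, low, high, expected):
        assert classify_mcl1_dependence(DepolarizationProfile("l", low, high)) == expected

    def test_monotone_in_high_dose(self, rng):
        """Raising the high-dose depolarization never flips dependent → independent.

        The rule is deliberately not monotone in the low dose: a sub-threshold
        dose-responsive line (e.g. 4%/8%) loses its dependent call if only the
        low-dose reading rises past the high-dose one (9%/8%).
        """
        for _ in range(200):
            low, high = rng.uniform(0, 20, size=2)
            before = classify_mcl1_dependence(DepolarizationProfile("l", low, high))
            bump_high = classify_mcl1_dependence(DepolarizationProfile("l", low, high + rng.uniform(0, 5)))
            if before == "dependent":
                assert bump_high == "dependent"
        assert classify_mcl1_dependence(DepolarizationProfile("l", 4.0, 8.0)) == "dependent"
        assert classify_mcl1_dependence(DepolarizationProfile("l", 9.0, 8.0)) == "independent"

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            DepolarizationProfile("l", 150.0, 0.0)
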