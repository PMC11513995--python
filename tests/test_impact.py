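"""Node-pair permutation importance: oracles, grouping, coverage contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metagraph.graphs import EdgeRecord, SampleGraph, assemble_graph
from metagraph.impact import (
    coverage_contrast,
    group_pairs,
    impact_scores,
    local_explanation,
    observed_weight_ranges,
)


def graph_from_weights(sample_id, weights: dict):
    """weights: {(species, knum): w}; plus a fixed habitat/env edge."""
    records = [EdgeRecord(s, k, w) for (s, k), w in weights.items() if w > 0]
    records.append(EdgeRecord("grassland", "temp_long", 8.0))
    return assemble_graph(records, set(), soc=0.0, sample_id=sample_id)


class LinearSurrogate:
    """f(G) = sum of coefficient * weight over configured pairs."""

    def __init__(self, coefficients: dict):
        self.coefficients = coefficients

    def predict(self, graphs):
        out = []
        for g in graphs:
            val = 0.0
            for (s, k), c in self.coefficients.items():
                w = g.edge_weight(s, k)
                val += c * (w if w is not None else 0.0)
            out.append(val)
        return np.array(out)


class QuadraticSurrogate:
    def predict(self, graphs):
        out = []
        for g in graphs:
            total = 0.0
            for (i, j), w in zip(g.edges.tolist(), g.weights.tolist()):
                if g.node_features[j, 0] or g.node_features[i, 0]:
                    total += 0.03 * w**2 - 0.5 * w
            out.append(np.tanh(total / 100) * 50)
        return np.array(out)


@pytest.fixture()
def surrogate_graphs():
    weight_sets = [
        {("A", "K00001"): 1.0, ("B", "K00002"): 5.0},
        {("A", "K00001"): 11.0, ("B", "K00002"): 5.0},
        {("A", "K00001"): 6.0, ("B", "K00002"): 5.0},
        {("A", "K00001"): 3.0},  # (B, K00002) absent: observed weight 0
        {("A", "K00001"): 2.0, ("B", "K00002"): 5.0},
    ]
    return [graph_from_weights(f"S{i}", ws) for i, ws in enumerate(weight_sets)]


class TestImpactScores:
    def test_linear_surrogate_closed_form(self, surrogate_graphs):
        model = LinearSurrogate({("A", "K00001"): 2.0, ("B", "K00002"): 0.5})
        table = impact_scores(model, surrogate_graphs)
        a = table[(table.source == "A") & (table.target == "K00001")].iloc[0]
        # observed weights of (A, K00001): 1..11 -> impact 2 * (11 - 1) = 20
        assert a["mean_impact"] == pytest.approx(20.0)
        assert a["sd_impact"] == pytest.approx(0.0, abs=1e-12)
        b = table[(table.source == "B") & (table.target == "K00002")].iloc[0]
        # (B, K00002): absent in S3 counts as 0 -> range 0..5 -> 0.5 * 5 = 2.5
        assert b["mean_impact"] == pytest.approx(2.5)
        assert b["sd_impact"] == pytest.approx(0.0, abs=1e-12)
        assert a["rank"] == 1 and b["rank"] == 2

    def test_constant_weight_pair_has_zero_impact(self):
        graphs = [
            graph_from_weights(f"S{i}", {("A", "K00001"): 7.0, ("B", "K00002"): float(i + 1)})
            for i in range(4)
        ]
        model = LinearSurrogate({("A", "K00001"): 3.0})
        table = impact_scores(model, graphs)
        row = table[(table.source == "A") & (table.target == "K00001")].iloc[0]
        assert row["mean_impact"] == 0.0 and row["sd_impact"] == 0.0

    def test_nonlinear_surrogate_matches_brute_force(self, surrogate_graphs):
        """Independent oracle: rebuild each substituted graph one at a time."""
        model = QuadraticSurrogate()
        table = impact_scores(model, surrogate_graphs)
        ranges = observed_weight_ranges(surrogate_graphs)
        for pair, (lo, hi) in ranges.items():
            row = table[(table.source == pair[0]) & (table.target == pair[1])].iloc[0]
            for g in surrogate_graphs:
                base = {
                    (g.node_names[i], g.node_names[j]): w
                    for (i, j), w in zip(g.edges.tolist(), g.weights.tolist())
                }
                canon = {}
                for (a, b), w in base.items():
                    canon[(b, a) if b < a else (a, b)] = w
                lo_w = dict(base)
                hi_w = dict(base)
                lo_w[pair], hi_w[pair] = lo, hi
                glo = assemble_graph(
                    [EdgeRecord(s, t, w) for (s, t), w in lo_w.items()], set(), 0.0, g.sample_id
                )
                ghi = assemble_graph(
                    [EdgeRecord(s, t, w) for (s, t), w in hi_w.items()], set(), 0.0, g.sample_id
                )
                expected = model.predict([ghi])[0] - model.predict([glo])[0]
                assert row[g.sample_id] == pytest.approx(expected, abs=1e-10)

    def test_requested_absent_pair_scores_zero(self, surrogate_graphs):
        model = LinearSurrogate({})
        table = impact_scores(model, surrogate_graphs, pairs=[("Z", "K09999")])
        assert table["mean_impact"].iloc[0] == 0.0

    def test_abs_rank_mode(self, surrogate_graphs):
        model = LinearSurrogate({("A", "K00001"): -2.0, ("B", "K00002"): 0.5})
        signed = impact_scores(model, surrogate_graphs, rank_mode="signed")
        absolute = impact_scores(model, surrogate_graphs, rank_mode="abs")
        assert signed.iloc[0]["source"] == "B"  # most positive first
        assert absolute.iloc[0]["source"] == "A"  # largest magnitude first


class TestGroupPairs:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["source", "target", "mean_impact"])

    def test_equal_means_one_group(self):
        recs = self._records([("A", "K1", 1.480), ("A", "K2", 1.480)])
        groups = group_pairs(recs, tolerance=0.01)
        assert len(groups) == 1
        assert len(groups[0]["pairs"]) == 2

    def test_distinct_means_split(self):
        recs = self._records([("A", "K1", 1.48), ("A", "K2", 1.45)])
        groups = group_pairs(recs, tolerance=0.01)
        assert len(groups) == 2

    def test_different_sources_never_merge(self):
        recs = self._records([("A", "K1", 1.0), ("B", "K2", 1.0)])
        assert len(group_pairs(recs, tolerance=0.5)) == 2

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in ("A", "B", "C"):
            base = rng.uniform(0, 3, size=3)
            for b in base:
                for _ in range(rng.integers(1, 4)):
                    rows.append((s, f"K{rng.integers(0, 99999):05d}", b + rng.normal(0, 1e-4)))
        recs = self._records(rows)
        tol = 0.01
        groups = group_pairs(recs, tolerance=tol)
        # every within-group spread respects the tolerance
        for g in groups:
            means = [
                recs[(recs.source == s) & (recs.target == t)]["mean_impact"].iloc[0]
                for s, t in g["pairs"]
            ]
            assert max(means) - min(means) <= tol + 1e-12
        # groups cover all pairs exactly once
        seen = [p for g in groups for p in g["pairs"]]
        assert len(seen) == len(recs) and len(set(seen)) == len(recs)


class TestCoverageContrast:
    def _pair_counts(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "species", "function", "count"])

    def test_identical_groups_give_t_zero(self):
        pairs = [("A", "K1")]
        counts = self._pair_counts([("S1", "A", "K1", 3), ("S2", "A", "K1", 2)])
        soc = pd.Series({"S1": 10.0, "S2": 12.0, "S3": 10.0, "S4": 12.0})
        res = coverage_contrast(pairs, counts, soc)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.df == 2
        assert res.mean_covered == res.mean_uncovered == 11.0

    def test_three_vs_three_hand_computed(self):
        pairs = [("A", "K1")]
        counts = self._pair_counts([(s, "A", "K1", 1) for s in ("S1", "S2", "S3")])
        soc = pd.Series({"S1": 10.0, "S2": 12.0, "S3": 14.0, "S4": 5.0, "S5": 6.0, "S6": 7.0})
        res = coverage_contrast(pairs, counts, soc)
        # pooled t: means 12 vs 6, s_p^2 = (2*4 + 2*1)/4 = 2.5, se = sqrt(2.5*2/3)
        expected_t = (12 - 6) / np.sqrt(2.5 * (1 / 3 + 1 / 3))
        assert res.t_statistic == pytest.approx(expected_t)
        assert res.df == 4
        scipy_res = stats.ttest_ind([10, 12, 14], [5, 6, 7], equal_var=True)
        assert res.t_statistic == pytest.approx(scipy_res.statistic)

    def test_empty_group_raises_with_counts(self):
        pairs = [("A", "K1")]
        counts = self._pair_counts([("S1", "A", "K1", 1), ("S2", "A", "K1", 1)])
        soc = pd.Series({"S1": 1.0, "S2": 2.0})
        with pytest.raises(ValueError, match="uncovered=0"):
            coverage_contrast(pairs, counts, soc)

    def test_planted_streamlined_pairs_separate_soc(self, small_cohort):
        """Covered samples of the planted pairs carry higher SOC."""
        truth = small_cohort["truth"]
        res = coverage_contrast(
            truth.streamlined_pairs,
            small_cohort["pairs"],
            small_cohort["metadata"]["soc"],
        )
        assert res.mean_covered > res.mean_uncovered
        assert res.t_statistic > 0


class TestLocalExplanation:
    def test_linear_surrogate_matches_global_column(self, surrogate_graphs):
        model = LinearSurrogate({("A", "K00001"): 2.0, ("B", "K00002"): 0.5})
        table = impact_scores(model, surrogate_graphs)
        local = local_explanation(model, surrogate_graphs, "S0", top_k=10)
        for row in local.itertuples(index=False):
            expected = table[(table.source == row.source) & (table.target == row.target)][
                "S0"
            ].iloc[0]
            assert row.impact == pytest.approx(expected)

    def test_k_zero_empty(self, surrogate_graphs):
        model = LinearSurrogate({})
        assert len(local_explanation(model, surrogate_graphs, "S0", top_k=0)) == 0

    def test_top_k_matches_brute_force(self, surrogate_graphs):
        model = QuadraticSurrogate()
        table = impact_scores(model, surrogate_graphs)
        local = local_explanation(model, surrogate_graphs, "S2", top_k=2)
        expected = table["S2"].abs().sort_values(ascending=False).head(2).tolist()
        assert local["impact"].abs().tolist() == pytest.approx(expected)

    def test_unknown_sample_rejected(self, surrogate_graphs):
        with pytest.raises(ValueError, match="nope"):
            local_explanation(LinearSurrogate({}), surrogate_graphs, "nope", top_k=1)
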