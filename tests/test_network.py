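"""Correlation P-values, network construction, hubs, and the tendency test."""

import numpy as np
import pandas as pd
import pytest

from famscan import (
    CorrelationRecord,
    HubCriteria,
    ParameterError,
    build_network,
    connected_components,
    correlation_pvalues,
    hub_genes,
    tendency_test,
)
from famscan.network import DEFAULT_CUTOFFS
from famscan.synthetic import generate_expression_matrix


def matrix(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"t{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=ids,
                        columns=[f"s{j}" for j in range(rows.shape[1])])


class TestCorrelationPvalues:
    def test_duplicated_row_perfect_correlation(self):
        m = matrix([[1, 2, 3, 4, 7], [1, 2, 3, 4, 7], [5, 1, 4, 2, 2]])
        recs = {(r.id_a, r.id_b): r for r in correlation_pvalues(m)}
        dup = recs[("t0", "t1")]
        assert dup.r == pytest.approx(1.0) and dup.p_value == 0.0

    def test_anticorrelated_pair(self):
        x = [1.0, 4.0, 2.0, 8.0]
        m = matrix([x, [-v for v in x]])
        rec = correlation_pvalues(m)[0]
        assert rec.r == pytest.approx(-1.0) and rec.p_value == 0.0

    def test_zero_variance_rows_excluded(self):
        m = matrix([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        recs = correlation_pvalues(m)
        ids = {r.id_a for r in recs} | {r.id_b for r in recs}
        assert "t0" not in ids and len(recs) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            correlation_pvalues(matrix([[1, 2], [3, 4]]))

    def test_type_one_error_calibrated(self, rng):
        """Independent rows: ~5% of pairs reach p <= 0.05 (n = 42)."""
        m = matrix(rng.standard_normal((60, 42)))
        recs = correlation_pvalues(m)
        frac = np.mean([r.p_value <= 0.05 for r in recs])
        assert 0.03 <= frac <= 0.07


def crec(a, b, p, r=0.5):
    return CorrelationRecord(a, b, r, 1.0, p, 42)


class TestBuildNetwork:
    def test_zero_cutoff_empty_network(self):
        g = build_network([crec("a", "b", 1e-300)], 0.0)
        assert g.number_of_edges() == 0

    def test_isolated_transcripts_excluded(self):
        g = build_network(
            [crec("a", "b", 1e-5), crec("a", "c", 0.5)], 1e-3
        )
        assert set(g.nodes) == {"a", "b"}

    def test_edge_sets_nested_across_cutoffs(self, planted_module):
        fam, bg, _ = planted_module
        recs = correlation_pvalues(pd.concat([fam.iloc[:10], bg.iloc[:20]]))
        prev = None
        for c in DEFAULT_CUTOFFS:  # descending
            edges = set(build_network(recs, c).edges)
            edges = {tuple(sorted(e)) for e in edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_planted_module_retained_at_stringent_cutoff(self, planted_module):
        fam, bg, truth = planted_module
        both = pd.concat([fam, bg.iloc[:40]])
        recs = correlation_pvalues(both)
        g = build_network(recs, 1e-8)
        fam_ids = truth.true_module_members
        # all planted-module pairs survive; background pairs do not
        for r in recs:
            if r.id_a in fam_ids and r.id_b in fam_ids:
                assert g.has_edge(r.id_a, r.id_b)
        for a, b in g.edges:
            assert a in fam_ids and b in fam_ids

    def test_degree_sum_is_twice_edges(self, planted_module):
        fam, _, _ = planted_module
        g = build_network(correlation_pvalues(fam), 1e-3)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestComponents:
    def test_two_disjoint_triangles(self):
        recs = [crec(a, b, 1e-9) for a, b in
                [("a", "b"), ("b", "c"), ("a", "c"),
                 ("x", "y"), ("y", "z"), ("x", "z")]]
        g = build_network(recs, 1e-3)
        labels, count = connected_components(g)
        assert count == 2
        assert labels["b"] == "a" and labels["z"] == "x"

    def test_empty_network(self):
        g = build_network([], 0.5)
        labels, count = connected_components(g)
        assert count == 0 and labels == {}

    def test_independent_planted_modules_separate(self):
        m1, _ = generate_expression_matrix(8, 0, module_correlation=0.95,
                                           seed=1)
        m2, _ = generate_expression_matrix(8, 0, module_correlation=0.95,
                                           seed=2)
        m2.index = [f"mod2_{i}" for i in range(8)]
        recs = correlation_pvalues(pd.concat([m1, m2]))
        g = build_network(recs, 1e-10)
        _, count = connected_components(g)
        assert count == 2


class TestHubGenes:
    def test_star_graph_center_is_hub(self):
        recs = [crec("hub", f"leaf{i:02d}", 1e-6) for i in range(40)]
        hubs = hub_genes(recs, HubCriteria(0.001, 30, 0.05))
        assert hubs == [("hub", 40)]

    def test_all_low_degree_no_hubs(self):
        recs = [crec(f"a{i}", f"b{i}", 1e-6) for i in range(20)]
        assert hub_genes(recs, HubCriteria(0.001, 30, 0.05)) == []

    def test_hub_fraction_cap(self):
        # 10 candidate hubs of degree 35 in a 100-node network, cap 5%
        recs = []
        hubs_wanted = [f"h{i}" for i in range(10)]
        others = [f"n{i:02d}" for i in range(90)]
        for h_idx, h in enumerate(hubs_wanted):
            for j in range(35):
                recs.append(crec(h, others[(h_idx * 7 + j) % 90], 1e-6))
        g = build_network(recs, 0.001)
        assert g.number_of_nodes() == 100
        hubs = hub_genes(recs, HubCriteria(0.001, 30, 0.05))
        assert len(hubs) == 5
        assert all(d >= 35 for _, d in hubs)

    def test_order_invariance(self):
        recs = [crec("hub", f"leaf{i:02d}", 1e-6) for i in range(40)]
        fwd = hub_genes(recs, HubCriteria(0.001, 30, 0.5))
        rev = hub_genes(list(reversed(recs)), HubCriteria(0.001, 30, 0.5))
        assert fwd == rev


class TestTendency:
    def test_deterministic_given_seed(self, planted_module):
        fam, bg, _ = planted_module
        a = tendency_test(fam, bg, subsample_size=15, n_reps=5, seed=77)
        b = tendency_test(fam, bg, subsample_size=15, n_reps=5, seed=77)
        assert np.array_equal(a.family_edge_counts, b.family_edge_counts)
        assert a.edge_p_values == b.edge_p_values

    def test_planted_module_detected_at_every_cutoff(self, planted_module):
        fam, bg, _ = planted_module
        res = tendency_test(fam, bg, subsample_size=30, n_reps=20, seed=5)
        assert all(p <= 0.01 for p in res.edge_p_values)
        # family networks are denser than controls throughout
        assert (res.family_edge_counts.mean(axis=0)
                >= res.control_edge_counts.mean(axis=0)).all()

    def test_null_data_mostly_nonsignificant(self):
        a, _ = generate_expression_matrix(30, 0, module_correlation=0.5,
                                          seed=900)
        # both "family" and control drawn from the independent background
        fam, _ = generate_expression_matrix(0, 30, module_correlation=0.5,
                                            seed=901)
        bg, _ = generate_expression_matrix(0, 60, module_correlation=0.5,
                                           seed=902)
        res = tendency_test(fam, bg, subsample_size=20,
                            cutoffs=[5e-2, 1e-2, 1e-3], n_reps=20, seed=6)
        signif = sum(p <= 0.05 for p in res.edge_p_values)
        assert signif <= 1

    def test_mismatched_samples_rejected(self, planted_module):
        fam, bg, _ = planted_module
        with pytest.raises(ParameterError):
            tendency_test(fam, bg.rename(columns={"S1": "weird"}),
                          subsample_size=10)

    def test_oversized_subsample_rejected(self, planted_module):
        fam, bg, _ = planted_module
        with pytest.raises(ParameterError):
            tendency_test(fam, bg, subsample_size=10_000)
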