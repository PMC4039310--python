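from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncoint import drug_network as dn
from oncoint import synthetic_data as sd
from oncoint.errors import InputError


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["compound_id", "target_protein", "allele", "affinity_type", "value", "source"],
    )


class TestFilterRecords:
    def test_kd_cutoff(self):
        recs = _records(
            [
                ("c1", "EGFR", "", "Kd", 50.0, "competition_assay"),
                ("c2", "EGFR", "", "Kd", 150.0, "competition_assay"),
            ]
        )
        out = dn.filter_records(recs)
        assert list(out["compound_id"]) == ["c1"]

    def test_bindingdb_cutoff(self):
        recs = _records(
            [
                ("c1", "EGFR", "", "IC50", 8.0, "bindingdb"),
                ("c2", "EGFR", "", "IC50", 12.0, "bindingdb"),
            ]
        )
        assert list(dn.filter_records(recs)["compound_id"]) == ["c1"]

    def test_boundary_strict(self):
        recs = _records(
            [
                ("c1", "EGFR", "", "Kd", 100.0, "competition_assay"),
                ("c2", "EGFR", "", "Kd", 99.9, "competition_assay"),
                ("c3", "EGFR", "", "Ki", 10.0, "bindingdb"),
                ("c4", "EGFR", "", "Ki", 9.9, "bindingdb"),
            ]
        )
        assert list(dn.filter_records(recs)["compound_id"]) == ["c2", "c4"]

    def test_drugbank_kept_on_presence(self):
        recs = _records([("c1", "GRB2", "", "presence", 0.0, "drugbank")])
        assert len(dn.filter_records(recs)) == 1

    def test_percent_inhibition_never_passes_filter(self):
        recs = _records([("c1", "EGFR", "", "percent_inhibition", 99.0, "kinase_assay")])
        assert len(dn.filter_records(recs)) == 0

    def test_unknown_source_warns(self):
        recs = _records([("c1", "EGFR", "", "Kd", 5.0, "mystery_db")])
        with pytest.warns(UserWarning, match="mystery_db"):
            assert len(dn.filter_records(recs)) == 0

    def test_idempotent(self):
        cfg = sd.SimulationConfig(seed=9)
        recs, _, _ = sd.simulate_drug_tables(cfg)
        once = dn.filter_records(recs)
        twice = dn.filter_records(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_order_invariant(self):
        cfg = sd.SimulationConfig(seed=9)
        recs, _, _ = sd.simulate_drug_tables(cfg)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = dn.filter_records(recs).sort_values(list(recs.columns)).reset_index(drop=True)
        b = dn.filter_records(shuffled).sort_values(list(recs.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestAlleleMatch:
    def test_allele_query(self):
        recs = _records(
            [
                ("c1", "EGFR", "T790M", "Kd", 5.0, "competition_assay"),
                ("c2", "EGFR", "", "Kd", 5.0, "competition_assay"),
            ]
        )
        assert list(dn.allele_match(recs, "EGFR", "T790M")["compound_id"]) == ["c1"]
        assert list(dn.allele_match(recs, "EGFR")["compound_id"]) == ["c2"]

    def test_planted_binders_recovered(self):
        cfg = sd.SimulationConfig(seed=10)
        recs, _, truth = sd.simulate_drug_tables(cfg)
        filtered = dn.filter_records(recs)
        target = next(iter(truth.true_allele_binders))[1]
        matched = dn.allele_match(filtered, target, "T790M")
        found = {(r.compound_id, r.target_protein, r.allele) for r in matched.itertuples(index=False)}
        assert found == truth.true_allele_binders


class TestBuildDrugNetwork:
    def test_proportions(self):
        recs = _records(
            [
                ("c1", "A", "", "Kd", 1.0, "competition_assay"),
                ("c2", "A", "", "Kd", 1.0, "competition_assay"),
                ("c3", "B", "", "Kd", 1.0, "competition_assay"),
            ]
        )
        result = dn.build_drug_network(recs, ["A", "B"])
        props = dict(zip(result.proportions["protein"], result.proportions["pct_of_compounds"]))
        assert props["A"] == pytest.approx(100 * 2 / 3)
        assert props["B"] == pytest.approx(100 / 3)
        assert result.n_compounds == 3

    def test_protein_without_compounds(self):
        recs = _records([("c1", "A", "", "Kd", 1.0, "competition_assay")])
        result = dn.build_drug_network(recs, ["A", "ARHG5"])
        row = result.proportions.set_index("protein").loc["ARHG5"]
        assert row["n_compounds"] == 0 and row["pct_of_compounds"] == 0.0
        assert result.graph.degree("ARHG5") == 0

    def test_bipartite(self):
        cfg = sd.SimulationConfig(seed=12)
        recs, _, _ = sd.simulate_drug_tables(cfg)
        result = dn.build_drug_network(dn.filter_records(recs), list(cfg.core_genes))
        kinds = nx.get_node_attributes(result.graph, "kind")
        for a, b in result.graph.edges():
            assert {kinds[a], kinds[b]} == {"compound", "protein"}

    def test_compound_node_count_matches_distinct(self):
        cfg = sd.SimulationConfig(seed=12)
        recs, _, _ = sd.simulate_drug_tables(cfg)
        result = dn.build_drug_network(dn.filter_records(recs), list(cfg.core_genes))
        n_nodes = sum(1 for _, k in result.graph.nodes(data="kind") if k == "compound")
        assert n_nodes == result.n_compounds

    def test_non_core_targets_excluded(self):
        recs = _records([("c1", "OFFTARGET", "", "Kd", 1.0, "competition_assay")])
        result = dn.build_drug_network(recs, ["A"])
        assert result.n_compounds == 0


def _chain(*nodes):
    g = nx.Graph()
    nx.add_path(g, nodes)
    return g


def _screening(rows):
    return pd.DataFrame(rows, columns=["compound_id", "kinase", "value"])


class TestDiffusionRank:
    def test_distance_zero_recovers_value(self):
        g = _chain("A", "B")
        scores = dn.diffusion_rank(g, _screening([("c", "A", 42.0)]))
        by_target = {s.target_protein: s.score for s in scores}
        assert by_target["A"] == pytest.approx(42.0)
        assert by_target["B"] == pytest.approx(21.0)

    def test_forced_arithmetic(self):
        # measurements 20 at d=0 and 90 at d=1 with alpha 0.5 -> 20 + 45 = 65
        g = _chain("K", "L")
        scores = dn.diffusion_rank(
            g, _screening([("c", "K", 20.0), ("c", "L", 90.0)]), alpha=0.5
        )
        by_target = {s.target_protein: s.score for s in scores}
        assert by_target["K"] == pytest.approx(65.0)

    def test_disconnected_scores_zero(self):
        g = _chain("A", "B")
        g.add_node("ISLAND")
        scores = dn.diffusion_rank(g, _screening([("c", "A", 10.0)]))
        by_target = {s.target_protein: s.score for s in scores}
        assert by_target["ISLAND"] == 0.0

    def test_monotone_decay_with_distance(self):
        g = _chain("A", "B", "C", "D", "E")
        scores = dn.diffusion_rank(g, _screening([("c", "A", 100.0)]), alpha=0.4)
        by_target = {s.target_protein: s.score for s in scores}
        values = [by_target[n] for n in "ABCDE"]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_adding_disconnected_node_changes_nothing(self):
        g = _chain("A", "B", "C")
        before = dn.diffusion_rank(g, _screening([("c", "A", 10.0)]))
        g.add_node("NEW")
        after = dn.diffusion_rank(g, _screening([("c", "A", 10.0)]))
        before_map = {(s.compound_id, s.target_protein): s.score for s in before}
        after_map = {(s.compound_id, s.target_protein): s.score for s in after}
        for key, value in before_map.items():
            assert after_map[key] == value
        assert after_map[("c", "NEW")] == 0.0

    def test_measured_kinase_absent_from_network(self):
        g = _chain("A", "B")
        scores = dn.diffusion_rank(
            g, _screening([("c", "A", 10.0), ("c", "GHOST", 99.0)])
        )
        by_target = {s.target_protein: s.score for s in scores}
        assert by_target["A"] == pytest.approx(10.0)

    def test_invalid_alpha(self):
        with pytest.raises(InputError):
            dn.diffusion_rank(_chain("A", "B"), _screening([("c", "A", 1.0)]), alpha=1.0)

    def test_bfs_brute_force_equivalence(self):
        """Exhaustive BFS oracle on random graphs with <= 8 nodes."""
        rng = np.random.default_rng(23)
        for trial in range(30):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            measured = [(f"n{i}", float(rng.uniform(0, 100))) for i in rng.choice(n, size=min(3, n), replace=False)]
            alpha = 0.5
            scores = dn.diffusion_rank(g, _screening([("c", k, v) for k, v in measured]), alpha=alpha)
            by_target = {s.target_protein: s.score for s in scores}

            # independent oracle: hand-rolled BFS
            def bfs_dist(src):
                dist = {src: 0}
                q = deque([src])
                while q:
                    u = q.popleft()
                    for v in g[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            q.append(v)
                return dist

            for target in g.nodes:
                expected = 0.0
                for k, value in measured:
                    d = bfs_dist(k).get(target)
                    if d is not None:
                        expected += value * alpha**d
                assert by_target[target] == pytest.approx(expected, rel=1e-12)


class TestSelectCandidates:
    def test_top_percentile(self):
        scores = [
            dn.DiffusionScore("c", f"t{i}", float(i), ()) for i in range(100)
        ]
        top = dn.select_candidates(scores, percentile=95.0)
        assert {s.target_protein for s in top} <= {f"t{i}" for i in range(95, 100)}

    def test_empty(self):
        assert dn.select_candidates([], percentile=95.0) == []


class TestCompoundCanonicalization:
    def test_salt_stripping_and_casefold(self):
        assert dn.canonical_compound("Imatinib Mesylate") == "imatinib"
        assert dn.canonical_compound("ERLOTINIB") == "erlotinib"

    def test_micromolar_conversion(self):
        recs = _records([("c1", "A", "", "Kd", 0.05, "competition_assay")])
        recs["unit"] = "uM"
        out = dn.micromolar_to_nanomolar(recs)
        assert out.loc[0, "value"] == pytest.approx(50.0)
        assert out.loc[0, "unit"] == "nM"


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["c1", "c2"]),
            st.sampled_from(["A", "B"]),
            st.sampled_from(["Kd", "Ki", "IC50", "presence"]),
            st.floats(min_value=0, max_value=500, allow_nan=False),
            st.sampled_from(["competition_assay", "kinase_assay", "bindingdb", "drugbank"]),
        ),
        max_size=15,
    )
)
def test_filter_idempotence_property(rows):
    recs = _records([(c, t, "", a, v, s) for c, t, a, v, s in rows])
    once = dn.filter_records(recs)
    twice = dn.filter_records(once)
    pd.testing.assert_frame_equal(once, twice)
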