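"""Co-occurrence networks: O/E ratios, filters, exclusivity, export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import comorbnet as cn
from comorbnet.network import network_to_frames, sex_exclusivity


def _frame(rows, conditions):
    """rows: list of (sex, set-of-conditions)."""
    data = {"sex": [r[0] for r in rows]}
    for c in conditions:
        data[c] = [int(c in r[1]) for r in rows]
    data["patient_id"] = [f"p{i}" for i in range(len(rows))]
    return pd.DataFrame(data)


def _catalog(conditions):
    return cn.ConditionCatalog.from_lists(chronic=list(conditions))


class TestPairwiseOE:
    def test_six_patient_toy(self):
        # 3 patients with both A and B, 3 with neither: O=3, E=3*3/6=1.5, O/E=2
        rows = [("female", {"A", "B"})] * 3 + [("female", set())] * 3
        edges = cn.pairwise_oe(_frame(rows, ["A", "B"]), _catalog(["A", "B"]))
        assert len(edges) == 1
        e = edges[0]
        assert (e.observed, e.expected, e.oe_ratio) == (3, 1.5, 2.0)
        assert e.pair_prevalence == pytest.approx(0.5)

    def test_ubiquitous_condition_forces_oe_one(self):
        rows = [("female", {"A", "B"}), ("female", {"A"}), ("female", {"A", "B"}),
                ("female", {"A"})]
        edges = cn.pairwise_oe(_frame(rows, ["A", "B"]), _catalog(["A", "B"]))
        assert edges[0].oe_ratio == pytest.approx(1.0)
        assert edges[0].observed == 2

    def test_empty_subcohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cn.pairwise_oe(_frame([], ["A"]), _catalog(["A", "B"]))

    def test_condition_absent_from_table_rejected(self):
        rows = [("female", {"A"})]
        with pytest.raises(KeyError, match="B"):
            cn.pairwise_oe(_frame(rows, ["A"]), _catalog(["A", "B"]))

    def test_independent_assignment_oe_near_one(self):
        rng = np.random.default_rng(17)
        n = 20_000
        df = pd.DataFrame({
            "sex": ["female"] * n,
            "A": (rng.random(n) < 0.3).astype(int),
            "B": (rng.random(n) < 0.3).astype(int),
        })
        edges = cn.pairwise_oe(df, _catalog(["A", "B"]))
        assert abs(edges[0].oe_ratio - 1.0) < 0.1

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sets(st.sampled_from(["A", "B", "C", "D", "E"])),
                    min_size=1, max_size=10))
    def test_matches_brute_force_on_tiny_cohorts(self, patient_sets):
        conditions = ["A", "B", "C", "D", "E"]
        rows = [("female", s) for s in patient_sets]
        edges = cn.pairwise_oe(_frame(rows, conditions), _catalog(conditions))
        got = {(e.condition_a, e.condition_b): e for e in edges}
        n = len(patient_sets)
        for a, b in itertools.combinations(conditions, 2):
            n_a = sum(1 for s in patient_sets if a in s)
            n_b = sum(1 for s in patient_sets if b in s)
            if n_a == 0 or n_b == 0:
                assert (a, b) not in got
                continue
            observed = sum(1 for s in patient_sets if a in s and b in s)
            expected = n_a * n_b / n
            e = got[(a, b)]
            assert e.observed == observed
            assert e.expected == pytest.approx(expected)
            assert e.oe_ratio == pytest.approx(observed * n / (n_a * n_b))

    def test_symmetry_under_column_order(self):
        rows = [("female", {"A", "B"}), ("female", {"B"}), ("female", set())]
        e1 = cn.pairwise_oe(_frame(rows, ["A", "B"]), _catalog(["A", "B"]))
        e2 = cn.pairwise_oe(_frame(rows, ["B", "A"]), _catalog(["B", "A"]))
        assert e1[0] == e2[0]

    def test_label_permutation_null_drives_oe_to_one(self):
        # shuffling each condition column independently preserves margins and
        # destroys association; mean |O/E - 1| shrinks with N
        rng = np.random.default_rng(23)
        devs = {}
        for n in (500, 20_000):
            base = {"sex": ["female"] * n}
            for j, c in enumerate("ABCD"):
                col = np.zeros(n, int)
                col[: int(n * 0.3)] = 1
                rng.shuffle(col)
                base[c] = col
            edges = cn.pairwise_oe(pd.DataFrame(base), _catalog(list("ABCD")))
            devs[n] = np.mean([abs(e.oe_ratio - 1) for e in edges])
        assert devs[20_000] < 0.1
        assert devs[20_000] < devs[500]


class TestBuildNetwork:
    def _df(self, n=1000, seed=0, p=(0.3, 0.3), rho_pairs=()):
        rng = np.random.default_rng(seed)
        df = {"sex": ["female"] * n}
        df["A"] = (rng.random(n) < p[0]).astype(int)
        df["B"] = (rng.random(n) < p[1]).astype(int)
        return pd.DataFrame(df)

    def test_node_prevalence_threshold_is_strict(self):
        rows = [("female", {"A"})] * 21 + [("female", {"B"})] * 19 \
            + [("female", set())] * 960
        df = _frame(rows, ["A", "B"])
        g = cn.build_network(df, _catalog(["A", "B"]), prevalence_threshold=0.02,
                             oe_threshold=0.0, drop_isolated=False)
        assert "A" in g.nodes  # 21/1000 = 0.021 > 0.02
        assert "B" not in g.nodes  # 19/1000 = 0.019

    def test_oe_exactly_two_removed_under_strict_filter(self):
        rows = [("female", {"A", "B"})] * 3 + [("female", set())] * 3
        df = _frame(rows, ["A", "B"])
        g = cn.build_network(df, _catalog(["A", "B"]), prevalence_threshold=0.0,
                             oe_threshold=2.0)
        assert g.number_of_edges() == 0
        g2 = cn.build_network(df, _catalog(["A", "B"]), prevalence_threshold=0.0,
                              oe_threshold=1.99)
        assert g2.number_of_edges() == 1

    def test_empty_edge_list_gives_empty_network(self):
        rows = [("female", {"A"}), ("female", {"B"})]
        g = cn.build_network(_frame(rows, ["A", "B"]), _catalog(["A", "B"]))
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_filter_monotonicity(self):
        rows = ([("female", {"A", "B"})] * 5 + [("female", {"B", "C"})] * 4
                + [("female", {"A"})] * 3 + [("female", set())] * 40)
        df = _frame(rows, ["A", "B", "C"])
        cat = _catalog(["A", "B", "C"])
        base = cn.build_network(df, cat, prevalence_threshold=0.01, oe_threshold=1.0)
        for pt, oe in [(0.05, 1.0), (0.01, 2.0), (0.08, 3.0)]:
            tighter = cn.build_network(df, cat, prevalence_threshold=pt, oe_threshold=oe)
            assert set(tighter.nodes) <= set(base.nodes)
            assert set(map(frozenset, tighter.edges)) <= set(map(frozenset, base.edges))

    def test_degree_recomputed_after_filtering(self):
        rows = [("female", {"A", "B"})] * 5 + [("female", set())] * 15
        g = cn.build_network(_frame(rows, ["A", "B"]), _catalog(["A", "B"]),
                             prevalence_threshold=0.0, oe_threshold=1.0)
        assert all(d["degree"] == g.degree(v) for v, d in g.nodes(data=True))


class TestPerSexNetworks:
    def _mixed(self):
        rows = ([("female", {"A", "B"})] * 6 + [("female", set())] * 6
                + [("male", {"A"})] * 2 + [("male", set())] * 10)
        return _frame(rows, ["A", "B"])

    def test_exclusivity_shares_sum_to_one(self):
        excl = sex_exclusivity(self._mixed(), _catalog(["A", "B"]))
        assert excl["female"]["A"] + excl["male"]["A"] == pytest.approx(1.0)
        assert excl["female"]["A"] == pytest.approx(6 / 8)
        assert excl["female"]["B"] == pytest.approx(1.0)

    def test_sex_with_no_patients_rejected(self):
        rows = [("female", {"A"})] * 3
        with pytest.raises(ValueError, match="male"):
            cn.per_sex_networks(_frame(rows, ["A"]), _catalog(["A"]))

    def test_networks_built_independently_per_sex(self):
        nets = cn.per_sex_networks(self._mixed(), _catalog(["A", "B"]),
                                   prevalence_threshold=0.0, oe_threshold=1.0)
        assert nets["female"].number_of_edges() == 1
        assert nets["male"].number_of_edges() == 0
        assert nets["female"].nodes["A"]["exclusivity"] == pytest.approx(0.75)


class TestExport:
    def _toy_network(self):
        rows = [("female", {"A", "B"})] * 3 + [("female", set())] * 3
        return cn.build_network(_frame(rows, ["A", "B"]), _catalog(["A", "B"]),
                                prevalence_threshold=0.0, oe_threshold=1.9)

    @pytest.mark.parametrize("fmt", ["graphml", "gexf"])
    def test_round_trip_preserves_attributes(self, tmp_path, fmt):
        g = self._toy_network()
        path = tmp_path / f"net.{fmt}"
        pos = {v: (float(i), float(-i)) for i, v in enumerate(g.nodes)}
        cn.export_network(g, path, fmt=fmt, positions=pos)
        back = cn.import_network(path, fmt=fmt)
        assert set(back.nodes) == set(g.nodes)
        e = back.edges["A", "B"]
        assert float(e["oe_ratio"]) == 2.0
        assert e["observed"] == 3
        for v in g.nodes:
            assert float(back.nodes[v]["x"]) == pos[v][0]
            assert float(back.nodes[v]["prevalence"]) == g.nodes[v]["prevalence"]

    def test_empty_network_exports_cleanly(self, tmp_path):
        g = nx.Graph()
        path = tmp_path / "empty.graphml"
        cn.export_network(g, path)
        assert cn.import_network(path).number_of_nodes() == 0

    def test_missing_positions_rejected(self, tmp_path):
        g = self._toy_network()
        with pytest.raises(ValueError, match="positions missing"):
            cn.export_network(g, tmp_path / "x.graphml", positions={"A": (0, 0)})

    def test_frames_dump(self):
        nodes, edges = network_to_frames(self._toy_network())
        assert list(edges["oe_ratio"]) == [2.0]
        assert set(nodes["condition"]) == {"A", "B"}
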