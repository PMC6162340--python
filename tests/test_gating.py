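"""Gating tree rollup, index joining, and enrichment correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shmstop.gating import (
    GateNode,
    GatingTree,
    join_index_data,
    leaf_frequency,
    rollup_frequency,
    tallies_from_cells,
)


def simple_tree(tallies=None):
    nodes = [
        GateNode("GC", None),
        GateNode("DZ", "GC", 0.6),
        GateNode("LZ", "GC", 0.4),
        GateNode("DZ_hi", "DZ", 0.8),
        GateNode("DZ_lo", "DZ", 0.2),
        GateNode("LZ_all", "LZ", 1.0),
    ]
    tree = GatingTree(nodes)
    if tallies is not None:
        tree.set_tallies(pd.DataFrame(tallies))
    return tree


class TestLeafFrequency:
    @pytest.mark.parametrize("n_stop,n_seq,expected", [
        (0, 25, 0.0), (3, 60, 5.0), (1, 1, 100.0),
    ])
    def test_values(self, n_stop, n_seq, expected):
        assert leaf_frequency(n_stop, n_seq) == pytest.approx(expected)

    def test_zero_sequenced_rejected(self):
        with pytest.raises(ValueError):
            leaf_frequency(0, 0)


class TestTreeValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="cover fraction"):
            GatingTree([GateNode("GC", None), GateNode("DZ", "GC", 0.6),
                        GateNode("LZ", "GC", 0.3)])

    def test_declared_covered_fraction_allows_partial(self):
        tree = GatingTree([GateNode("GC", None), GateNode("DZ", "GC", 0.6),
                           GateNode("LZ", "GC", 0.3)],
                          covered_fractions={"GC": 0.9})
        assert tree.leaves() == ["DZ", "LZ"]

    def test_single_root_required(self):
        with pytest.raises(ValueError, match="root"):
            GatingTree([GateNode("A", None), GateNode("B", None)])

    def test_stop_exceeding_sequenced_rejected(self):
        with pytest.raises(ValueError, match="n_stop"):
            GateNode("x", None, n_sequenced=5, n_stop=6)

    def test_yaml_round_trip(self, tmp_path):
        tree = simple_tree([{"gate": "DZ_hi", "n_sequenced": 100, "n_stop": 2},
                            {"gate": "DZ_lo", "n_sequenced": 50, "n_stop": 9},
                            {"gate": "LZ_all", "n_sequenced": 80, "n_stop": 1}])
        path = tmp_path / "tree.yaml"
        tree.to_yaml(path)
        back = GatingTree.from_yaml(path)
        assert back.leaves() == tree.leaves()
        assert back.nodes["DZ_lo"].n_stop == 9
        assert back.nodes["DZ"].fraction_of_parent == 0.6


class TestRollup:
    def test_two_leaf_weighted_sum(self):
        # 10% and 2% with fractions 0.2/0.8 -> 3.6%
        tree = GatingTree([GateNode("P", None),
                           GateNode("a", "P", 0.2, n_sequenced=100, n_stop=10),
                           GateNode("b", "P", 0.8, n_sequenced=100, n_stop=2)])
        est = rollup_frequency(tree, "P")
        assert est.frequency == pytest.approx(3.6)
        assert est.n_effective == 200
        assert set(est.leaves_used) == {"a", "b"}

    def test_four_quadrant_formula_instantiation(self):
        """The cell-cycle-quadrant rollup equals direct evaluation of the
        four-term weighted-sum formula."""
        fracs = {"q_early_g1": 0.30, "q_late_g1": 0.40, "q_s": 0.20, "q_g2m": 0.10}
        tallies = {"q_early_g1": (40, 2), "q_late_g1": (50, 9),
                   "q_s": (30, 1), "q_g2m": (20, 4)}
        nodes = [GateNode("BCRlow_DZ", None)]
        for name, frac in fracs.items():
            n, k = tallies[name]
            nodes.append(GateNode(name, "BCRlow_DZ", frac,
                                  n_sequenced=n, n_stop=k))
        est = rollup_frequency(GatingTree(nodes), "BCRlow_DZ")
        direct = sum(fracs[g] * 100.0 * tallies[g][1] / tallies[g][0]
                     for g in fracs)
        assert est.frequency == pytest.approx(direct)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0.0, 100.0))
    def test_convexity_identity(self, f):
        """All leaves at frequency f put every internal node at f."""
        n = 1000
        k = round(n * f / 100)
        tree = simple_tree([{"gate": g, "n_sequenced": n, "n_stop": k}
                            for g in ("DZ_hi", "DZ_lo", "LZ_all")])
        for node in ("GC", "DZ", "LZ"):
            assert rollup_frequency(tree, node).frequency == \
                pytest.approx(100.0 * k / n)

    def test_flattened_weighted_sum_equals_recursive(self):
        """Order independence: GC from (DZ, LZ) equals one flat sum over
        leaves with product weights."""
        tree = simple_tree([{"gate": "DZ_hi", "n_sequenced": 200, "n_stop": 5},
                            {"gate": "DZ_lo", "n_sequenced": 150, "n_stop": 24},
                            {"gate": "LZ_all", "n_sequenced": 300, "n_stop": 4}])
        est = rollup_frequency(tree, "GC")
        flat = (0.6 * 0.8 * (100 * 5 / 200)
                + 0.6 * 0.2 * (100 * 24 / 150)
                + 0.4 * 1.0 * (100 * 4 / 300))
        assert est.frequency == pytest.approx(flat)

    def test_proportional_sampling_equals_pooled(self):
        """With sequencing proportional to gate fractions, rollup equals the
        naive pooled frequency."""
        # fractions 0.8/0.2 and sequencing 400/100 cells (proportional)
        tree = GatingTree([GateNode("P", None),
                           GateNode("a", "P", 0.8, n_sequenced=400, n_stop=8),
                           GateNode("b", "P", 0.2, n_sequenced=100, n_stop=10)])
        est = rollup_frequency(tree, "P")
        pooled = 100.0 * (8 + 10) / 500
        assert est.frequency == pytest.approx(pooled)

    def test_oversampled_rare_leaf_corrected(self):
        """10x oversampling of a rare 17.2%-truth leaf biases pooling but not
        the rollup."""
        rng = np.random.default_rng(99)
        n_hi, n_lo = 170, 330  # 10x enrichment of the 0.16-fraction leaf
        k_hi = rng.binomial(n_hi, 0.022)
        k_lo = rng.binomial(n_lo, 0.172)
        tree = GatingTree([GateNode("DZ", None),
                           GateNode("hi", "DZ", 0.84, n_sequenced=n_hi, n_stop=int(k_hi)),
                           GateNode("lo", "DZ", 0.16, n_sequenced=n_lo, n_stop=int(k_lo))])
        est = rollup_frequency(tree, "DZ")
        truth = 0.84 * 2.2 + 0.16 * 17.2  # 4.6%
        pooled = 100.0 * (k_hi + k_lo) / (n_hi + n_lo)
        assert est.ci_low <= truth <= est.ci_high
        assert abs(pooled - truth) > (est.ci_high - est.ci_low)

    def test_missing_leaf_error_lists_gaps(self):
        tree = simple_tree([{"gate": "DZ_hi", "n_sequenced": 10, "n_stop": 0}])
        with pytest.raises(ValueError, match="DZ_lo"):
            rollup_frequency(tree, "GC")

    def test_missing_leaf_renormalize(self):
        tree = simple_tree([{"gate": "DZ_hi", "n_sequenced": 100, "n_stop": 10},
                            {"gate": "LZ_all", "n_sequenced": 100, "n_stop": 0}])
        est = rollup_frequency(tree, "DZ", missing_leaf_policy="renormalize")
        assert est.frequency == pytest.approx(10.0)  # DZ_lo's weight redistributed

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            rollup_frequency(simple_tree(), "nope")


class TestJoin:
    def _index(self, ids):
        return pd.DataFrame({"cell_id": ids,
                             "gate": ["DZ_hi"] * len(ids),
                             "channel_bcr": np.linspace(0, 1, len(ids))})

    def _calls(self, ids, stops=None):
        stops = stops or [False] * len(ids)
        return pd.DataFrame({"cell_id": ids, "has_premature_stop": stops})

    def test_disjoint_ids_empty_join(self):
        joined, report = join_index_data(self._index(["a", "b"]),
                                         self._calls(["c", "d"]))
        assert len(joined) == 0
        assert report["unmatched_index"] == ["a", "b"]
        assert report["unmatched_calls"] == ["c", "d"]

    def test_full_match_preserves_columns(self):
        ids = [f"c{i}" for i in range(100)]
        joined, report = join_index_data(self._index(ids), self._calls(ids))
        assert len(joined) == 100 and report["n_matched"] == 100
        assert {"gate", "channel_bcr", "has_premature_stop"} <= set(joined.columns)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            join_index_data(self._index(["a", "a"]), self._calls(["a"]))

    def test_tallies_from_cells_match_truth(self):
        ids = [f"c{i}" for i in range(10)]
        stops = [True, False, False, True, False, False, False, False, False, False]
        joined, _ = join_index_data(self._index(ids), self._calls(ids, stops))
        tal = tallies_from_cells(joined)
        assert tal.loc[0, "gate"] == "DZ_hi"
        assert tal.loc[0, "n_sequenced"] == 10
        assert tal.loc[0, "n_stop"] == 2

    def test_null_stop_status_dropped_from_tallies(self):
        ids = ["a", "b", "c"]
        calls = pd.DataFrame({"cell_id": ids,
                              "has_premature_stop": [True, None, False]})
        joined, _ = join_index_data(self._index(ids), calls)
        tal = tallies_from_cells(joined)
        assert tal.loc[0, "n_sequenced"] == 2 and tal.loc[0, "n_stop"] == 1
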