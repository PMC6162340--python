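"""Gate-weighted frequency normalization for index-sorted populations.

During index sorting, rare gates (e.g. BCR-low dark-zone cells) are
deliberately oversampled so that enough of them are sequenced.  The naive
pooled stop-codon frequency over sequenced cells is therefore biased toward
those gates.  The correction weights each leaf gate's observed frequency by
its *pre-enrichment* cytometry fraction of the parent population:

    frequency(parent) = sum_children frequency(child) * fraction_of_parent(child)

applied recursively up the gating tree (e.g. BCR subsets -> DZ, then
DZ/LZ/CXCR4-low CD83-low remainder -> whole germinal center).

Per-leaf binomial uncertainty uses Wilson score intervals, propagated to
parents with the same weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import yaml
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GateNode",
    "GatingTree",
    "PopulationEstimate",
    "leaf_frequency",
    "rollup_frequency",
    "join_index_data",
    "tallies_from_cells",
]

FRACTION_TOL = 1e-6


@dataclass
class GateNode:
    name: str
    parent: str | None
    fraction_of_parent: float = 1.0
    n_sequenced: int | None = None
    n_stop: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.fraction_of_parent <= 1.0):
            raise ValueError(f"gate {self.name}: fraction_of_parent outside [0, 1]")
        if self.n_stop is not None and self.n_sequenced is not None:
            if self.n_stop > self.n_sequenced:
                raise ValueError(f"gate {self.name}: n_stop > n_sequenced")


@dataclass(frozen=True)
class PopulationEstimate:
    name: str
    frequency: float        # percent
    n_effective: int        # total sequenced cells contributing
    leaves_used: tuple[str, ...]
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.frequency <= 100.0):
            raise ValueError("frequency must be a percentage in [0, 100]")


class GatingTree:
    """Nested gates with pre-enrichment fractions and leaf sequencing tallies.

    ``covered_fraction`` may be declared on a parent whose listed children
    deliberately cover only part of it; otherwise children's fractions must
    sum to 1.
    """

    def __init__(self, nodes: Sequence[GateNode],
                 covered_fractions: Mapping[str, float] | None = None):
        self.nodes: dict[str, GateNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate gate name {node.name!r}")
            self.nodes[node.name] = node
        self.covered_fractions = dict(covered_fractions or {})
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root gate, found {len(roots)}")
        self.root = roots[0].name
        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise ValueError(f"gate {node.name}: unknown parent {node.parent!r}")
                self._children[node.parent].append(node.name)
        self._validate_fractions()

    def _validate_fractions(self):
        for parent, kids in self._children.items():
            if not kids:
                continue
            total = sum(self.nodes[k].fraction_of_parent for k in kids)
            expected = self.covered_fractions.get(parent, 1.0)
            if abs(total - expected) > FRACTION_TOL:
                raise ValueError(
                    f"children of {parent!r} cover fraction {total:.6f}, expected {expected:.6f}"
                )

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def is_leaf(self, name: str) -> bool:
        return not self._children[name]

    def leaves(self, below: str | None = None) -> list[str]:
        start = below or self.root
        out, stack = [], [start]
        while stack:
            n = stack.pop()
            kids = self._children[n]
            if kids:
                stack.extend(reversed(kids))
            else:
                out.append(n)
        return out

    def set_tallies(self, tallies: pd.DataFrame) -> None:
        """Attach leaf tallies from a DataFrame with columns
        ``gate``, ``n_sequenced``, ``n_stop``."""
        for _, row in tallies.iterrows():
            gate = row["gate"]
            if gate not in self.nodes:
                raise ValueError(f"tally for unknown gate {gate!r}")
            if not self.is_leaf(gate):
                raise ValueError(f"tally attached to non-leaf gate {gate!r}")
            self.nodes[gate].n_sequenced = int(row["n_sequenced"])
            self.nodes[gate].n_stop = int(row["n_stop"])

    # -- serialization --------------------------------------------------

    @classmethod
    def from_dicts(cls, records: Sequence[dict]) -> "GatingTree":
        covered = {}
        nodes = []
        for rec in records:
            rec = dict(rec)
            cf = rec.pop("covered_fraction", None)
            node = GateNode(
                name=rec["name"], parent=rec.get("parent"),
                fraction_of_parent=float(rec.get("fraction_of_parent", 1.0)),
                n_sequenced=rec.get("n_sequenced"), n_stop=rec.get("n_stop"),
            )
            if cf is not None:
                covered[node.name] = float(cf)
            nodes.append(node)
        return cls(nodes, covered)

    @classmethod
    def from_yaml(cls, path) -> "GatingTree":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dicts(data["gates"] if isinstance(data, dict) else data)

    def to_dicts(self) -> list[dict]:
        out = []
        for node in self.nodes.values():
            rec = {"name": node.name, "parent": node.parent,
                   "fraction_of_parent": node.fraction_of_parent}
            if node.name in self.covered_fractions:
                rec["covered_fraction"] = self.covered_fractions[node.name]
            if node.n_sequenced is not None:
                rec["n_sequenced"] = node.n_sequenced
                rec["n_stop"] = node.n_stop
            out.append(rec)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"gates": self.to_dicts()}, fh, sort_keys=False)


def leaf_frequency(n_stop: int, n_sequenced: int) -> float:
    """Observed stop frequency of a leaf, percent."""
    if n_sequenced <= 0:
        raise ValueError("n_sequenced must be positive")
    if not (0 <= n_stop <= n_sequenced):
        raise ValueError("n_stop must be in [0, n_sequenced]")
    return 100.0 * n_stop / n_sequenced


def _wilson(n_stop: int, n_sequenced: int) -> tuple[float, float]:
    low, high = proportion_confint(n_stop, n_sequenced, alpha=0.05, method="wilson")
    return 100.0 * low, 100.0 * high


def rollup_frequency(tree: GatingTree, node: str,
                     missing_leaf_policy: str = "error") -> PopulationEstimate:
    """Enrichment-corrected stop frequency of ``node``.

    Recursively weights each child's frequency by its pre-enrichment
    fraction of the parent.  Leaves must carry tallies; leaves without data
    either raise (``"error"``, listing the gaps) or have their fractions
    renormalized over their sequenced siblings (``"renormalize"``).
    """
    if node not in tree.nodes:
        raise KeyError(f"unknown gate {node!r}")
    if missing_leaf_policy not in ("error", "renormalize"):
        raise ValueError("missing_leaf_policy must be 'error' or 'renormalize'")

    missing = [leaf for leaf in tree.leaves(node)
               if tree.nodes[leaf].n_sequenced is None]
    if missing and missing_leaf_policy == "error":
        raise ValueError(f"leaves without sequencing data under {node!r}: {missing}")

    def _roll(name: str) -> tuple[float, float, float, int, tuple[str, ...]] | None:
        n = tree.nodes[name]
        if tree.is_leaf(name):
            if n.n_sequenced is None or n.n_sequenced == 0:
                return None
            freq = leaf_frequency(n.n_stop, n.n_sequenced)
            low, high = _wilson(n.n_stop, n.n_sequenced)
            return freq, low, high, n.n_sequenced, (name,)
        parts = []
        for child in tree.children(name):
            sub = _roll(child)
            if sub is not None:
                parts.append((tree.nodes[child].fraction_of_parent, sub))
        if not parts:
            return None
        wsum = sum(w for w, _ in parts)
        declared = tree.covered_fractions.get(name, 1.0)
        if abs(wsum - declared) > FRACTION_TOL:
            if missing_leaf_policy == "error":
                raise ValueError(f"missing data under {name!r}")
            parts = [(w / wsum * declared, sub) for w, sub in parts]
        freq = sum(w * sub[0] for w, sub in parts) / declared
        low = sum(w * sub[1] for w, sub in parts) / declared
        high = sum(w * sub[2] for w, sub in parts) / declared
        n_eff = sum(sub[3] for _, sub in parts)
        leaves = tuple(l for _, sub in parts for l in sub[4])
        return freq, low, high, n_eff, leaves

    result = _roll(node)
    if result is None:
        raise ValueError(f"no sequencing data anywhere under {node!r}")
    freq, low, high, n_eff, leaves = result
    return PopulationEstimate(node, freq, n_eff, leaves, low, high)


def join_index_data(index_table: pd.DataFrame, call_table: pd.DataFrame,
                    key: str = "cell_id") -> tuple[pd.DataFrame, dict]:
    """Inner-join indexed FACS data with per-cell stop calls.

    Both tables must be keyed by a unique ``cell_id``.  Returns the joined
    table and a report of unmatched ids on each side.
    """
    for name, df in (("index table", index_table), ("call table", call_table)):
        dups = df[key][df[key].duplicated()].tolist()
        if dups:
            raise ValueError(f"duplicate {key} in {name}: {sorted(set(dups))[:5]}")
    joined = index_table.merge(call_table, on=key, how="inner",
                               suffixes=("_index", "_calls"))
    report = {
        "n_matched": len(joined),
        "unmatched_index": sorted(set(index_table[key]) - set(call_table[key])),
        "unmatched_calls": sorted(set(call_table[key]) - set(index_table[key])),
    }
    return joined, report


def tallies_from_cells(joined: pd.DataFrame, gate_col: str = "gate",
                       stop_col: str = "has_premature_stop") -> pd.DataFrame:
    """Per-gate (n_sequenced, n_stop) tallies from a joined per-cell table.

    Cells with a null stop status (e.g. unalignable sequences) are dropped
    from both counts.
    """
    usable = joined[joined[stop_col].notna()]
    tallies = (usable.groupby(gate_col)
                     .agg(n_sequenced=(stop_col, "size"),
                          n_stop=(stop_col, lambda s: int(s.astype(bool).sum())))
                     .reset_index()
                     .rename(columns={gate_col: "gate"}))
    return tallies
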