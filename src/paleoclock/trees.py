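"""Rooted time-calibrated trees (chronograms) with per-branch rates.

A :class:`TimeTree` stores a rooted topology in flat arrays: ``parent`` links,
node ages in Ga before present (leaves at 0, ages strictly increasing toward
the root) and, optionally, a substitution rate for the branch above each
non-root node in amino-acid substitutions per site per Ga.  The expected
number of substitutions per site on a branch is rate x duration, which is the
branch length written to Newick output.

Newick parsing/serialisation is delegated to dendropy.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

NO_PARENT = -1


class TreeStructureError(ValueError):
    """Violation of chronogram invariants (age ordering, missing rates...)."""


class TimeTree:
    """Array-backed rooted chronogram.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``NO_PARENT`` for the root.
    children : list of child-index lists.
    age : (n_nodes,) float array, Ga before present.
    branch_rate : (n_nodes,) float array; rate of the branch above each node
        (δ Ga⁻¹); NaN when unset and for the root.
    node_log_rate : (n_nodes,) float array of node log-rates for the
        autocorrelated clock parameterisation; NaN when unset.
    names : list of leaf names (None for internal nodes).
    labels : mapping from textual node label ("dup", "mrca_A"...) to node index.
    """

    def __init__(
        self,
        parent: Sequence[int],
        age: Sequence[float],
        names: Sequence[str | None],
        branch_rate: Sequence[float] | None = None,
        node_log_rate: Sequence[float] | None = None,
        labels: dict[str, int] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        n = self.parent.size
        self.age = np.asarray(age, dtype=float).copy()
        self.names = list(names)
        self.branch_rate = (
            np.full(n, np.nan) if branch_rate is None
            else np.asarray(branch_rate, dtype=float).copy()
        )
        self.node_log_rate = (
            np.full(n, np.nan) if node_log_rate is None
            else np.asarray(node_log_rate, dtype=float).copy()
        )
        self.labels = dict(labels or {})
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = None
        for i, p in enumerate(self.parent):
            if p == NO_PARENT:
                if root is not None:
                    raise TreeStructureError("multiple roots")
                root = i
            else:
                self.children[p].append(i)
        if root is None:
            raise TreeStructureError("no root node")
        self.root = root
        self._postorder: list[int] | None = None
        self.validate(require_rates=False)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def postorder(self) -> list[int]:
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for c in self.children[node]:
                        stack.append((c, False))
            self._postorder = order
        return self._postorder

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def validate(self, require_rates: bool = True) -> None:
        for i, p in enumerate(self.parent):
            if p != NO_PARENT and not self.age[p] > self.age[i]:
                raise TreeStructureError(
                    f"parent age {self.age[p]} not greater than child age "
                    f"{self.age[i]} at node {i}"
                )
        for leaf in self.leaves:
            if self.age[leaf] != 0.0:
                raise TreeStructureError(f"leaf {leaf} has non-zero age")
        if require_rates:
            for i in range(self.n_nodes):
                if i == self.root:
                    continue
                if not np.isfinite(self.branch_rate[i]) or self.branch_rate[i] <= 0:
                    raise TreeStructureError(f"branch above node {i} has no valid rate")

    def branch_duration(self, node: int) -> float:
        p = self.parent[node]
        if p == NO_PARENT:
            raise TreeStructureError("root has no parent branch")
        return float(self.age[p] - self.age[node])

    def branch_subs(self, node: int) -> float:
        """Expected substitutions/site on the branch above ``node``."""
        return self.branch_rate[node] * self.branch_duration(node)

    def branch_midpoint_age(self, node: int) -> float:
        p = self.parent[node]
        return float(0.5 * (self.age[p] + self.age[node]))

    def mrca(self, leaf_names: Iterable[str]) -> int:
        """Most recent common ancestor of the named leaves."""
        wanted = set(leaf_names)
        found = [i for i in self.leaves if self.names[i] in wanted]
        missing = wanted - {self.names[i] for i in found}
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        ancestors = set()
        node = found[0]
        while node != NO_PARENT:
            ancestors.add(node)
            node = self.parent[node]
        mrca = None
        for leaf in found[1:]:
            node = leaf
            while node not in ancestors:
                node = self.parent[node]
            # prune ancestors below this meeting point
            ancestors = {a for a in ancestors if self._is_ancestor_or_self(node, a)}
        # the mrca is the deepest member of the surviving ancestor chain
        mrca = min(ancestors, key=lambda a: self.age[a])
        return mrca

    def _is_ancestor_or_self(self, node: int, candidate: int) -> bool:
        a = node
        while a != NO_PARENT:
            if a == candidate:
                return True
            a = self.parent[a]
        return False

    def clade_leaves(self, node: int) -> list[int]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.append(v)
        return out

    def copy(self) -> "TimeTree":
        return TimeTree(
            self.parent.copy(),
            self.age.copy(),
            list(self.names),
            self.branch_rate.copy(),
            self.node_log_rate.copy(),
            dict(self.labels),
        )

    # ------------------------------------------------------------------ newick
    def to_newick(self, lengths: str = "subs") -> str:
        """Serialise to Newick.

        ``lengths='subs'`` writes expected substitutions/site (requires rates);
        ``lengths='time'`` writes branch durations in Ga (a chronogram).
        """
        if lengths not in ("subs", "time"):
            raise ValueError("lengths must be 'subs' or 'time'")

        def fmt(node: int) -> str:
            if self.children[node]:
                inner = ",".join(fmt(c) for c in self.children[node])
                label = ""
                for key, idx in self.labels.items():
                    if idx == node:
                        label = key
                        break
                body = f"({inner}){label}"
            else:
                body = self.names[node]
            if self.parent[node] == NO_PARENT:
                return body
            if lengths == "time":
                bl = self.branch_duration(node)
            else:
                bl = self.branch_subs(node)
            return f"{body}:{bl:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, lengths: str = "time") -> "TimeTree":
        """Build a TimeTree from a rooted Newick string whose branch lengths
        are durations in Ga (``lengths='time'``).  The tree must be
        ultrametric: leaf ages are set to 0 and internal ages accumulate
        durations tip-ward; inconsistent leaf depths raise
        :class:`TreeStructureError` (tolerance 1e-8 Ga).
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        dnodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        n = len(dnodes)
        parent = np.full(n, NO_PARENT, dtype=int)
        names: list[str | None] = [None] * n
        durations = np.zeros(n)
        labels: dict[str, int] = {}
        for nd in dnodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                durations[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                names[i] = nd.taxon.label.replace(" ", "_")
            elif nd.label:
                labels[nd.label] = i
        # depth from root, then age = max_depth - depth
        depth = np.zeros(n)
        for nd in dnodes:
            i = index[id(nd)]
            if parent[i] != NO_PARENT:
                depth[i] = depth[parent[i]] + durations[i]
        leaf_idx = [i for i in range(n) if names[i] is not None]
        max_depth = depth[leaf_idx].max()
        if np.ptp(depth[leaf_idx]) > 1e-8:
            raise TreeStructureError("tree is not ultrametric; cannot assign ages")
        age = max_depth - depth
        age[leaf_idx] = 0.0
        return cls(parent, age, names, labels=labels)


def rate_table(tree: TimeTree):
    """Per-branch table: child node, name/label, ages, duration, rate, subs."""
    import pandas as pd

    rows = []
    label_of = {idx: key for key, idx in tree.labels.items()}
    for node in range(tree.n_nodes):
        if tree.parent[node] == NO_PARENT:
            continue
        rows.append(
            {
                "node": node,
                "name": tree.names[node] or label_of.get(node, ""),
                "child_age_Ga": tree.age[node],
                "parent_age_Ga": tree.age[tree.parent[node]],
                "midpoint_age_Ga": tree.branch_midpoint_age(node),
                "duration_Ga": tree.branch_duration(node),
                "rate_subs_per_site_per_Ga": tree.branch_rate[node],
                "expected_subs_per_site": tree.branch_subs(node)
                if np.isfinite(tree.branch_rate[node])
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
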