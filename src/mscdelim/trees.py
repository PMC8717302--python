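"""Rooted species trees and per-locus gene genealogies.

Both tree kinds are stored as flat integer/float arrays (parent, children,
node ages) because the MCMC kernels index them millions of times; dendropy
is used only at the Newick boundary.

Conventions
-----------
* A :class:`SpeciesTree` over ``S`` candidate species has ``2S - 1`` nodes:
  tips ``0 .. S-1`` (in the order given by ``labels``) and internal nodes
  ``S .. 2S-2``.  Every node carries a population-size parameter ``theta``
  (4Nu per site) for the branch above it — the root's theta is the ancestral
  population — and every internal node carries a divergence time ``tau``
  in expected substitutions per site.  Tip tau is 0 by definition.
* A :class:`GeneTree` over ``n`` sampled sequences has ``2n - 1`` nodes:
  tips ``0 .. n-1`` with age 0, internal coalescent events above.  Tips map
  to species-tree tips through ``tip_species``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "GeneTree"]


class SpeciesTree:
    """Rooted binary tree over candidate species with tau/theta parameters.

    Parameters
    ----------
    labels : sequence of str
        Tip labels; tip ``i`` is ``labels[i]``.
    parent : array of int
        Parent index per node, ``-1`` for the root.
    left, right : arrays of int
        Child indices per node, ``-1`` for tips.
    tau : array of float, optional
        Divergence time per node (0 at tips), expected substitutions/site.
    theta : array of float, optional
        Population-size parameter per node branch (4Nu per site).
    """

    def __init__(self, labels, parent, left, right, tau=None, theta=None):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        n = self.n_nodes
        self.tau = None if tau is None else np.asarray(tau, dtype=np.float64)
        self.theta = None if theta is None else np.asarray(theta, dtype=np.float64)
        roots = np.nonzero(self.parent == -1)[0]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if n != 2 * self.n_tips - 1:
            raise ValueError("tree is not binary (node count != 2*tips - 1)")
        self._depth = np.zeros(n, dtype=np.int64)
        for v in self.preorder():
            if self.parent[v] >= 0:
                self._depth[v] = self._depth[self.parent[v]] + 1
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != self.n_tips:
            raise ValueError("duplicate tip labels")
        self.validate()

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, v: int) -> bool:
        return self.left[v] < 0

    def tip_index(self, label: str) -> int:
        return self._index[label]

    def preorder(self):
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if self.left[v] >= 0:
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        return order

    def postorder(self):
        return self.preorder()[::-1]

    def mrca(self, a: int, b: int) -> int:
        """Most recent common ancestor of nodes ``a`` and ``b``."""
        while a != b:
            if self._depth[a] >= self._depth[b]:
                a = int(self.parent[a])
            else:
                b = int(self.parent[b])
        return a

    def tips_below(self, v: int):
        """Tip indices in the clade rooted at ``v``."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.append(int(self.left[u]))
                stack.append(int(self.right[u]))
        return sorted(out)

    def validate(self):
        """Check tau ordering (parent above children) and positive theta."""
        if self.tau is not None:
            for v in range(self.n_nodes):
                if self.is_tip(v) and self.tau[v] != 0.0:
                    raise ValueError(f"tip {self.labels[v]!r} has nonzero tau")
                p = self.parent[v]
                if p >= 0 and not self.is_tip(v) and self.tau[p] <= self.tau[v]:
                    raise ValueError(
                        "tau ordering violated: node %d (tau=%g) under parent %d (tau=%g)"
                        % (v, self.tau[v], p, self.tau[p])
                    )
        if self.theta is not None and np.any(self.theta <= 0):
            raise ValueError("all theta must be > 0")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse a rooted binary Newick string.

        tau/theta may be carried in ``[&theta=...,tau=...]`` node comments;
        if absent the corresponding arrays are ``None``.
        """
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "SpeciesTree":
        leaves = [lf for lf in dt.leaf_node_iter()]
        internals = [nd for nd in dt.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError(
                    "non-binary node with %d children" % len(nd.child_nodes())
                )
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        index.update({id(nd): len(leaves) + i for i, nd in enumerate(internals)})
        n = 2 * len(leaves) - 1
        parent = np.full(n, -1, dtype=np.int64)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        tau = np.zeros(n)
        theta = np.zeros(n)
        have_tau = have_theta = False
        for nd in dt.preorder_node_iter():
            v = index[id(nd)]
            ann = {a.name: a.value for a in nd.annotations}
            if "tau" in ann:
                tau[v] = float(ann["tau"])
                have_tau = True
            if "theta" in ann:
                theta[v] = float(ann["theta"])
                have_theta = True
            ch = nd.child_nodes()
            if ch:
                left[v], right[v] = index[id(ch[0])], index[id(ch[1])]
                parent[left[v]] = parent[right[v]] = v
        return cls(
            labels,
            parent,
            left,
            right,
            tau=tau if have_tau else None,
            theta=theta if have_theta else None,
        )

    def to_newick(self, annotations: bool = True) -> str:
        """Serialize to Newick; tau/theta go into ``[&...]`` node comments."""

        def rec(v):
            parts = []
            if self.is_tip(v):
                core = self.labels[v]
            else:
                core = "(%s,%s)" % (rec(int(self.left[v])), rec(int(self.right[v])))
            ann = []
            if annotations and self.theta is not None:
                ann.append("theta=%.10g" % self.theta[v])
            if annotations and self.tau is not None and not self.is_tip(v):
                ann.append("tau=%.10g" % self.tau[v])
            comment = "[&%s]" % ",".join(ann) if ann else ""
            p = self.parent[v]
            if p >= 0 and self.tau is not None:
                bl = ":%.10g" % (self.tau[p] - self.tau[v])
            else:
                bl = ""
            return core + comment + bl

        return rec(self.root) + ";"

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(
            self.labels,
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
            tau=None if self.tau is None else self.tau.copy(),
            theta=None if self.theta is None else self.theta.copy(),
        )

    def __repr__(self):
        return "SpeciesTree(%d tips: %s)" % (self.n_tips, ",".join(self.labels[:6]))


@dataclass
class GeneTree:
    """A rooted binary genealogy over sampled sequence copies.

    Node ages are in expected substitutions per site; tips have age 0.
    ``tip_species[i]`` is the species-tree tip index of sequence ``i``.
    """

    tip_labels: list
    tip_species: np.ndarray
    age: np.ndarray
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.age)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    def postorder(self):
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            if self.left[v] >= 0:
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        return order[::-1]

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        return float(self.age[p] - self.age[v]) if p >= 0 else 0.0

    def path_length(self, a: int, b: int) -> float:
        """Patristic distance between two nodes."""
        anc_a = {}
        x, d = a, 0.0
        while x != -1:
            anc_a[x] = d
            if self.parent[x] >= 0:
                d += self.age[self.parent[x]] - self.age[x]
            x = int(self.parent[x])
        x, d = b, 0.0
        while x not in anc_a:
            d += self.age[self.parent[x]] - self.age[x]
            x = int(self.parent[x])
        return d + anc_a[x]

    def copy(self) -> "GeneTree":
        return GeneTree(
            list(self.tip_labels),
            self.tip_species.copy(),
            self.age.copy(),
            self.parent.copy(),
            self.left.copy(),
            self.right.copy(),
        )

    def to_newick(self) -> str:
        def rec(v):
            if self.left[v] < 0:
                core = str(self.tip_labels[v])
            else:
                core = "(%s,%s)" % (rec(int(self.left[v])), rec(int(self.right[v])))
            p = self.parent[v]
            bl = ":%.10g" % (self.age[p] - self.age[v]) if p >= 0 else ""
            return core + bl

        return rec(self.root) + ";"
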