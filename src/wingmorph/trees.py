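"""Phylogenies: pure-birth simulation, Newick IO, Brownian covariance.

Trees are held as :class:`dendropy.Tree` objects wrapped in a small
:class:`Phylogeny` record.  Under Brownian motion on an ultrametric tree the
expected covariance of a trait value between tips i and j is proportional to
C_ij, the root-to-MRCA path length shared by the two tips; :func:`phylo_covariance`
computes that N x N matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np


@dataclass
class Phylogeny:
    """A rooted tree with unique tip names and (time-unit) branch lengths."""

    tree: dendropy.Tree
    tip_names: list[str]

    @property
    def depth(self) -> float:
        return float(max(self._tip_depths().values()))

    def _node_depths(self) -> dict:
        depths = {}
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    def _tip_depths(self) -> dict:
        depths = self._node_depths()
        return {lf.taxon.label: depths[lf] for lf in self.tree.leaf_node_iter()}

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = np.array(list(self._tip_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        text = str(source)
        if "(" not in text and len(text) < 4096 and Path(text).exists():
            tree = dendropy.Tree.get(path=text, schema="newick")
        else:
            tree = dendropy.Tree.get(data=text, schema="newick")
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValueError("tip names must be unique")
        return cls(tree=tree, tip_names=tips)


@dataclass
class PhyloCovariance:
    """Shared-branch-length matrix under Brownian motion; C_ij is the depth
    (from the root) of the most recent common ancestor of tips i and j."""

    C: np.ndarray
    tip_order: list[str]


def simulate_tree(n_species: int, tree_depth: float = 10.0,
                  seed: int = 0, prefix: str = "sp") -> Phylogeny:
    """Simulate a pure-birth (Yule) topology, rescaled to total depth
    ``tree_depth`` so the result is exactly ultrametric.

    The default depth of 10 time units mirrors a 10 Ma basal-node
    calibration.  Deterministic for a given ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, _birth = active.pop(idx)
        node.edge.length = t - _birth
        k1, k2 = dendropy.Node(), dendropy.Node()
        node.add_child(k1)
        node.add_child(k2)
        active.extend([(k1, t), (k2, t)])
    total = t + rng.exponential(1.0 / len(active))
    taxa = dendropy.TaxonNamespace()
    for i, (node, birth) in enumerate(active):
        node.edge.length = total - birth
        node.taxon = taxa.new_taxon(f"{prefix}{i + 1:02d}")
    tree.taxon_namespace = taxa

    scale = tree_depth / total
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return Phylogeny(tree=tree, tip_names=tips)


def pectinate_tree(n_species: int, tree_depth: float = 10.0,
                   prefix: str = "sp") -> Phylogeny:
    """Fully imbalanced (comb/pectinate) ultrametric tree with splits at
    equal time intervals — maximal phylogenetic structure for its size."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    dt = tree_depth / (n_species - 1)
    tree = dendropy.Tree()
    taxa = dendropy.TaxonNamespace()
    node = tree.seed_node                       # depth (i - 1) * dt at step i
    for i in range(1, n_species):
        tip = dendropy.Node()
        node.add_child(tip)
        tip.taxon = taxa.new_taxon(f"{prefix}{i:02d}")
        tip.edge.length = tree_depth - (i - 1) * dt
        if i < n_species - 1:
            inner = dendropy.Node()
            node.add_child(inner)
            inner.edge.length = dt
            node = inner
        else:
            tip2 = dendropy.Node()
            node.add_child(tip2)
            tip2.taxon = taxa.new_taxon(f"{prefix}{n_species:02d}")
            tip2.edge.length = tree_depth - (i - 1) * dt
    tree.taxon_namespace = taxa
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return Phylogeny(tree=tree, tip_names=tips)


def star_tree(n_species: int, depth: float = 10.0, prefix: str = "sp") -> Phylogeny:
    """Star phylogeny (single polytomy at the root)."""
    newick = "(" + ",".join(
        f"{prefix}{i + 1:02d}:{depth:.10f}" for i in range(n_species)) + ");"
    return Phylogeny.from_newick(newick)


def phylo_covariance(phylogeny: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance structure of a rooted tree.

    Raises on negative branch lengths; warns (but proceeds) if the tree is
    not ultrametric.
    """
    tree = phylogeny.tree
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    if not phylogeny.is_ultrametric(rel_tol=1e-6):
        warnings.warn("tree is not ultrametric; C computed from actual depths")

    depths = phylogeny._node_depths()
    tips = phylogeny.tip_names
    index = {name: i for i, name in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    # leaves under each node, accumulated postorder
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = [index[nd.taxon.label]]
        else:
            kids = [below[ch] for ch in nd.child_nodes()]
            merged = [i for k in kids for i in k]
            below[nd] = merged
            d = depths[nd]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
    for lf in tree.leaf_node_iter():
        i = index[lf.taxon.label]
        C[i, i] = depths[lf]
    return PhyloCovariance(C=C, tip_order=list(tips))
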