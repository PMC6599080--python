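"""Phylogeny container and tree algebra shared across modules.

Wraps a dendropy tree and exposes the matrices the comparative methods
need: the Brownian-motion covariance (shared root-to-MRCA path lengths),
patristic distances, and Abouheif's oriented proximities.  Newick I/O
treats internal node labels as branch supports (e.g. SH-aLRT on 0-100).
"""

from __future__ import annotations

import io
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """Rooted tree with tip labels, branch lengths and optional supports."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.tips: list[str] = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if len(self.tips) != len(set(self.tips)):
            raise ValueError("duplicate tip labels")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    @classmethod
    def read_newick(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    # -- basic properties --------------------------------------------------
    def __len__(self) -> int:
        return len(self.tips)

    @property
    def n_internal(self) -> int:
        return sum(1 for n in self._tree.preorder_node_iter() if not n.is_leaf())

    def root_to_tip_depths(self) -> np.ndarray:
        """Root-to-tip distances in tip order."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        depth = {leaf.taxon.label: leaf.root_distance
                 for leaf in self._tree.leaf_node_iter()}
        return np.array([depth[t] for t in self.tips])

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.root_to_tip_depths()
        return bool(np.allclose(d, d.mean(), rtol=rtol, atol=rtol * max(d.mean(), 1.0)))

    def depth(self) -> float:
        return float(self.root_to_tip_depths().max())

    # -- matrices ----------------------------------------------------------
    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path-length (patristic) distances, tip order."""
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace
                if any(t.label == tip for tip in self.tips)}
        n = len(self.tips)
        out = np.zeros((n, n))
        for i, a in enumerate(self.tips):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[self.tips[j]])
                out[i, j] = out[j, i] = d
        return out

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared path length from root to MRCA.

        V[i, j] = (depth_i + depth_j - d_ij) / 2 with d the patristic
        distance; the diagonal holds the root-to-tip depths.
        """
        depths = self.root_to_tip_depths()
        d = self.patristic_matrix()
        v = (depths[:, None] + depths[None, :] - d) / 2.0
        np.fill_diagonal(v, depths)
        return v

    def abouheif_proximity(self) -> np.ndarray:
        """Oriented Abouheif proximities A[i, j] = 1 / prod(dd(node)).

        The product runs over the internal nodes on the path between tips i
        and j (MRCA included); dd is each node's number of direct
        descendants.  Diagonal is zero.
        """
        tree = self._tree
        leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        # ancestor chains root->tip
        chains = {}
        for lab, leaf in leaves.items():
            chain = []
            node = leaf
            while node is not None:
                chain.append(node)
                node = node.parent_node
            chains[lab] = chain[::-1]  # root first
        dd = {id(n): len(n.child_nodes()) for n in tree.preorder_node_iter()}
        n = len(self.tips)
        A = np.zeros((n, n))
        for i, a in enumerate(self.tips):
            ca = chains[a]
            for j in range(i + 1, n):
                cb = chains[self.tips[j]]
                k = 0
                while k < min(len(ca), len(cb)) and ca[k] is cb[k]:
                    k += 1
                # path: nodes from MRCA (index k-1) down both sides, tips excluded
                path_nodes = ca[k - 1:-1] + cb[k:-1]
                prod = 1.0
                for node in path_nodes:
                    prod *= dd[id(node)]
                A[i, j] = A[j, i] = 1.0 / prod
        return A

    # -- supports ----------------------------------------------------------
    def node_supports(self) -> list[float | None]:
        """Support values (parsed from internal node labels), preorder."""
        vals = []
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            lab = node.label
            try:
                vals.append(float(lab) if lab is not None else None)
            except ValueError:
                vals.append(None)
        return vals

    def trait_vector(self, table) -> np.ndarray:
        """Align a mapping/Series of tip -> value to this tree's tip order."""
        missing = [t for t in self.tips if t not in table]
        if missing:
            raise ValueError(f"trait values missing for tips: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        return np.array([float(table[t]) for t in self.tips])
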