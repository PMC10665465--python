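"""Dated ultrametric trees over genera.

A :class:`DatedTree` wraps a rooted :class:`dendropy.Tree` whose branch
lengths are in Ma, validates ultrametricity, and exposes the handful of
dated-tree operations the pipeline needs: stem ages, attachment of
unsampled genera at family/order crown nodes, and seed-reproducible
stochastic resolution of polytomies.

Node times are expressed in Ma before present ("age"); absolute time
("depth") runs from 0 at the root to the tree height at the present.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

__all__ = ["DatedTree", "parse_newick", "write_newick"]

#: relative tolerance for declaring tip depths equal (ultrametricity check)
ULTRAMETRIC_RTOL = 1e-6


class NotUltrametricError(ValueError):
    pass


class DatedTree:
    """A rooted, dated, ultrametric tree with genus tip labels.

    Parameters
    ----------
    tree
        A dendropy tree with branch lengths in Ma. The tree is used
        in place (not copied).
    taxonomy
        Optional mapping ``genus -> (family, order)`` used when
        attaching unsampled genera.
    validate
        If true (default), require all tips to be equidistant from the
        root within a relative tolerance of 1e-6.
    """

    def __init__(self, tree: dendropy.Tree, taxonomy: dict | None = None,
                 validate: bool = True):
        tree.is_rooted = True
        self.tree = tree
        self.taxonomy = dict(taxonomy) if taxonomy else {}
        self._refresh()
        if validate:
            self._check_ultrametric()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, taxonomy: dict | None = None,
                    validate: bool = True) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"newick parse error: {exc}") from exc
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError(
                    "newick parse error: missing branch length on edge to "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
                )
        return cls(tree, taxonomy=taxonomy, validate=validate)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
        )
        return s.strip() + "\n"

    def copy(self) -> "DatedTree":
        return DatedTree(self.tree.clone(depth=1), taxonomy=self.taxonomy,
                         validate=False)

    # -- cached geometry ---------------------------------------------------

    def _refresh(self) -> None:
        """Recompute node depths/ages after any topology change."""
        depth = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        self._depth = depth
        leaves = self.tree.leaf_node_iter()
        self.height = max(depth[lf] for lf in leaves)
        self._tip_index = {lf.taxon.label: lf for lf in self.tree.leaf_node_iter()}

    def _check_ultrametric(self) -> None:
        scale = max(self.height, 1e-12)
        for lf in self.tree.leaf_node_iter():
            if abs(self._depth[lf] - self.height) > ULTRAMETRIC_RTOL * scale:
                raise NotUltrametricError(
                    f"tree is not ultrametric: tip {lf.taxon.label!r} at depth "
                    f"{self._depth[lf]:g} vs height {self.height:g}"
                )

    # -- queries -----------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_index)

    def __len__(self) -> int:
        return len(self._tip_index)

    def depth(self, node) -> float:
        """Absolute time of ``node`` measured from the root (Ma)."""
        return self._depth[node]

    def age(self, node) -> float:
        """Time of ``node`` before present (Ma)."""
        return self.height - self._depth[node]

    def tip_node(self, label: str):
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"tip {label!r} not in tree") from None

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        if len(labels) == 1:
            return self.tip_node(labels[0])
        taxa = [self.tip_node(l).taxon for l in labels]
        return self.tree.mrca(taxa=taxa)

    def stem_age(self, tip: str) -> float:
        """Age of the branching event separating ``tip`` from its sister.

        This is the node time of the tip's parent — the "genus age" used
        throughout the assemblage analyses.
        """
        node = self.tip_node(tip)
        if node.parent_node is None:
            raise ValueError(f"tip {tip!r} has no parent (single-tip tree)")
        return self.age(node.parent_node)

    # -- grafting unsampled genera ----------------------------------------

    def _crown_node(self, rank: str, name: str):
        """Crown node of the named family/order: MRCA of its >=2 sampled tips."""
        idx = 0 if rank == "family" else 1
        members = [g for g, fo in self.taxonomy.items()
                   if fo[idx] == name and g in self._tip_index]
        if len(members) < 2:
            return None
        return self.mrca(members)

    def attach_unsampled(self, additions: list[tuple[str, str, str]]) -> "DatedTree":
        """Graft genera without data onto family (or order) crown nodes.

        Each addition is ``(genus, family, order)``. The genus becomes a
        new child of the family's crown node with a pendant branch equal
        to the crown age, creating/expanding a polytomy; if the family has
        fewer than two sampled members its order crown is used instead.
        Existing branch lengths are never altered. Returns self.
        """
        for genus, family, order in additions:
            crown = self._crown_node("family", family)
            if crown is None:
                crown = self._crown_node("order", order)
            if crown is None:
                raise ValueError(
                    f"no crown node for genus {genus!r}: family {family!r} and "
                    f"order {order!r} each have <2 sampled members"
                )
            taxon = dendropy.Taxon(label=genus)
            self.tree.taxon_namespace.add_taxon(taxon)
            crown.new_child(taxon=taxon, edge_length=self.age(crown))
            self._refresh()
        return self

    # -- polytomy resolution ----------------------------------------------

    def resolve_polytomies(self, seed: int) -> "DatedTree":
        """Resolve all polytomies into a random binary, ultrametric tree.

        Children of each polytomy are joined pairwise in uniform-random
        order (a coalescent-style sequence of joins); each new internal
        node's time is drawn uniformly strictly between its parent's time
        and the older of its two children. Pre-existing node times and the
        tip set are untouched; identical seeds give identical trees.
        Returns self.
        """
        rng = np.random.default_rng(seed)
        # stable processing order: preorder as constructed
        polytomies = [nd for nd in self.tree.preorder_node_iter()
                      if len(nd.child_nodes()) > 2]
        for node in polytomies:
            parent_age = self.age(node)
            pool = list(node.child_nodes())
            for ch in pool:
                node.remove_child(ch)
            while len(pool) > 2:
                i, j = sorted(rng.choice(len(pool), size=2, replace=False))
                a, b = pool[i], pool[j]
                child_age = max(self._subtree_root_age(a), self._subtree_root_age(b))
                t = rng.uniform(child_age, parent_age)
                join = dendropy.Node()
                join._pending_age = t
                for ch in (a, b):
                    join.add_child(ch)
                    ch.edge.length = t - self._subtree_root_age(ch)
                pool = [p for k, p in enumerate(pool) if k not in (i, j)]
                pool.append(join)
            for ch in pool:
                node.add_child(ch)
                ch.edge.length = parent_age - self._subtree_root_age(ch)
        self._finalize_pending_ages()
        self._refresh()
        return self

    def _subtree_root_age(self, node) -> float:
        if hasattr(node, "_pending_age"):
            return node._pending_age
        return self.age(node)

    def _finalize_pending_ages(self):
        for nd in self.tree.preorder_node_iter():
            if hasattr(nd, "_pending_age"):
                del nd._pending_age

    def is_binary(self) -> bool:
        return all(len(nd.child_nodes()) in (0, 2)
                   for nd in self.tree.preorder_node_iter())


def parse_newick(text: str, taxonomy: dict | None = None) -> DatedTree:
    """Parse a newick string (branch lengths in Ma) into a validated DatedTree."""
    return DatedTree.from_newick(text, taxonomy=taxonomy, validate=True)


def write_newick(tree: DatedTree) -> str:
    return tree.to_newick()
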