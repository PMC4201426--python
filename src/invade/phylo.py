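"""Tree I/O and per-species evolutionary metrics.

A :class:`Phylogeny` wraps a rooted :class:`dendropy.Tree` with branch
lengths in time units (here Myr) and exposes the per-tip quantities the
downstream analyses consume:

* **BL** — terminal (pendant) branch length, a species' "evolutionary age";
* **ED** — fair-proportion evolutionary distinctiveness: every branch's
  length is split equally among the tips descending from it, and each tip
  sums its shares along the path to the root.  Summed over tips, ED equals
  the total branch length of the tree exactly — a conservation law used as
  a correctness check throughout the test suite;
* the cophenetic (patristic) distance matrix needed by the community
  structure indices.

Trees need not be ultrametric.  Polytomies are accepted here (fair
proportion and path distances are well defined); modules that require a
strictly bifurcating tree enforce that themselves.
"""

from __future__ import annotations

import io
import os
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "read_newick",
    "normalize_name",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a species name: strip, collapse whitespace runs to '_'.

    Makes ``"Sus scrofa"`` and ``"Sus_scrofa"`` compare equal, the usual
    mismatch between Newick tip labels and tabular species columns.
    Case is preserved.
    """
    return _WS.sub("_", name.strip())


class Phylogeny:
    """A rooted tree with branch lengths and uniquely named tips.

    Parameters
    ----------
    tree
        A rooted ``dendropy.Tree``.  Every non-root edge must carry a
        finite, non-negative length (use ``default_edge_length`` in
        :func:`read_newick` to fill missing ones).  Tip labels are
        normalized on construction and must be unique afterwards.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        seen: set[str] = set()
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("every tip must be labeled")
            label = normalize_name(leaf.taxon.label)
            if label in seen:
                raise ValueError(f"duplicate tip name after normalization: {label!r}")
            seen.add(label)
            leaf.taxon.label = label

        # Postorder index: tips first encounter their parents later, so any
        # node's children precede it in `self._nodes`.
        self._nodes = list(tree.postorder_node_iter())
        self._index = {id(n): i for i, n in enumerate(self._nodes)}
        m = len(self._nodes)
        self._parent = np.full(m, -1, dtype=np.intp)
        self._blen = np.zeros(m, dtype=float)
        self._children: list[list[int]] = [[] for _ in range(m)]
        for i, node in enumerate(self._nodes):
            if node.parent_node is not None:
                p = self._index[id(node.parent_node)]
                self._parent[i] = p
                self._children[p].append(i)
                length = node.edge.length
                if length is None:
                    raise ValueError(
                        f"missing branch length on edge above "
                        f"{node.taxon.label if node.taxon else 'an internal node'}"
                    )
                if not np.isfinite(length) or length < 0:
                    raise ValueError(f"branch length must be finite and >= 0, got {length}")
                self._blen[i] = float(length)
        self._tip_ids = np.array(
            [i for i, n in enumerate(self._nodes) if n.is_leaf()], dtype=np.intp
        )
        self._tip_names = [self._nodes[i].taxon.label for i in self._tip_ids]
        self._tip_pos = {name: k for k, name in enumerate(self._tip_names)}

    # ------------------------------------------------------------------ #
    # basic structure

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self._tip_ids)

    @property
    def tip_names(self) -> list[str]:
        return list(self._tip_names)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths."""
        return float(self._blen.sum())

    def is_bifurcating(self) -> bool:
        """True if every internal node (root included) has exactly two children."""
        return all(len(c) in (0, 2) for c in self._children)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, total length {self.total_length:.4g}>"

    # ------------------------------------------------------------------ #
    # per-tip metrics

    def terminal_branch_lengths(self) -> dict[str, float]:
        """BL: length of each tip's pendant edge, keyed by tip name."""
        return {
            self._nodes[i].taxon.label: float(self._blen[i]) for i in self._tip_ids
        }

    def fair_proportion_ed(self) -> dict[str, float]:
        """Fair-proportion evolutionary distinctiveness per tip.

        Each edge contributes ``length / n_descendant_tips`` to every tip
        below it; a tip's ED is the sum of those shares along its root
        path.  Conservation: ``sum(ED) == total_length`` exactly (up to
        float rounding).
        """
        m = len(self._nodes)
        ntips_below = np.zeros(m, dtype=float)
        for i in range(m):  # postorder: children before parents
            kids = self._children[i]
            ntips_below[i] = 1.0 if not kids else sum(ntips_below[k] for k in kids)
        share = np.where(ntips_below > 0, self._blen / np.maximum(ntips_below, 1), 0.0)
        # accumulate root->tip in reverse postorder (parents before children)
        acc = np.zeros(m, dtype=float)
        for i in range(m - 1, -1, -1):
            p = self._parent[i]
            acc[i] = share[i] + (acc[p] if p >= 0 else 0.0)
        return {self._nodes[i].taxon.label: float(acc[i]) for i in self._tip_ids}

    def tip_metrics(self) -> pd.DataFrame:
        """DataFrame indexed by species with columns ``BL`` and ``ED``."""
        bl = self.terminal_branch_lengths()
        ed = self.fair_proportion_ed()
        df = pd.DataFrame({"BL": pd.Series(bl), "ED": pd.Series(ed)})
        df.index.name = "species"
        return df

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Symmetric tip-by-tip matrix of path lengths (patristic distances).

        Computed by one sweep over internal nodes: two tips whose lowest
        common ancestor is node *v* are at distance
        ``depth(i) + depth(j) - 2 depth(v)`` where depth is root-to-node
        path length.
        """
        m = len(self._nodes)
        depth = np.zeros(m, dtype=float)
        for i in range(m - 1, -1, -1):
            p = self._parent[i]
            depth[i] = self._blen[i] + (depth[p] if p >= 0 else 0.0)
        n = self.n_tips
        out = np.zeros((n, n), dtype=float)
        tip_depth = depth[self._tip_ids]
        # tips-below sets, assembled postorder
        below: list[np.ndarray | None] = [None] * m
        for i in range(m):
            kids = self._children[i]
            if not kids:
                below[i] = np.array([self._tip_pos[self._nodes[i].taxon.label]])
                continue
            parts = [below[k] for k in kids]
            for a in range(len(parts)):
                for b in range(a + 1, len(parts)):
                    ii = parts[a]
                    jj = parts[b]
                    d = tip_depth[ii][:, None] + tip_depth[jj][None, :] - 2.0 * depth[i]
                    out[np.ix_(ii, jj)] = d
                    out[np.ix_(jj, ii)] = d.T
            below[i] = np.concatenate(parts)
            for k in kids:
                below[k] = None  # free
        return pd.DataFrame(out, index=self._tip_names, columns=self._tip_names)

    # ------------------------------------------------------------------ #
    # manipulation / output

    def restrict_to(self, species) -> "Phylogeny":
        """Prune the tree down to the given species (names normalized).

        Raises ``ValueError`` if fewer than two requested species are on
        the tree.
        """
        keep = {normalize_name(s) for s in species} & set(self._tip_names)
        if len(keep) < 2:
            raise ValueError("fewer than two requested species are present on the tree")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return Phylogeny(clone)

    def resolve_polytomies(self, seed: int) -> "Phylogeny":
        """Randomly bifurcate polytomies with zero-length edges (seeded)."""
        import random

        clone = self._tree.clone(depth=1)
        clone.resolve_polytomies(limit=2, update_bipartitions=False,
                                 rng=random.Random(seed))
        for edge in clone.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
        return Phylogeny(clone)

    def write_newick(self, path: str | os.PathLike | None = None) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 unquoted_underscores=True)
        if path is not None:
            Path(path).write_text(s)
        return s


def read_newick(source: str | os.PathLike | io.IOBase,
                default_edge_length: float | None = None) -> Phylogeny:
    """Read a Newick tree from a path, a literal Newick string, or a handle.

    Branch lengths are required on all non-root edges; a missing length is
    an error unless ``default_edge_length`` supplies a fill-in value.
    Tip names are whitespace/underscore-normalized; duplicates after
    normalization are rejected.
    """
    if isinstance(source, io.IOBase):
        text = source.read()
    else:
        s = str(source)
        if "(" in s and ";" in s:
            text = s
        else:
            text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick input: {exc}") from exc
    if default_edge_length is not None:
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = default_edge_length
    return Phylogeny(tree)
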