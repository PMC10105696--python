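"""Neighbour-joining phenograms from Mahalanobis distance matrices.

Phenotypic similarity between groups is summarised by the Mahalanobis
distances between group means; the saturated distance matrix is rendered as an
unrooted neighbour-joining tree (Saitou-Nei), serialised to newick.  NJ is
consistent: on an additive matrix it reconstructs the generating tree exactly.
Tie-breaking in the Q-matrix minimisation is deterministic (lowest index pair
in sorted-label order), so the same matrix always yields the same tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    #: branch lengths before clamping negatives to zero, keyed by child id
    pre_clamp: dict[int, float] = field(default_factory=dict)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhenoTree:
    """Unrooted tree over group labels with nonnegative branch lengths."""

    root: TreeNode
    labels: list[str]
    clamped_edges: list[tuple[str, float]] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick(node: TreeNode) -> str:
    if not node.children:
        return _quote(node.label)
    inner = ",".join(f"{_newick(c)}:{length:.10g}" for c, length in node.children)
    label = _quote(node.label) if node.label else ""
    return f"({inner}){label}"


def write_newick(tree: PhenoTree, path: str | Path | None = None) -> str:
    """Serialise the tree as a newick string; optionally write it to a file."""
    text = _newick(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def neighbor_joining(distances, labels=None) -> PhenoTree:
    """Saitou-Nei neighbour joining of a symmetric distance matrix.

    Input labels are processed in sorted order and ties in the Q-matrix are
    broken toward the lowest index pair, so the output is deterministic and
    invariant (up to isomorphism) to the input label ordering.  Negative
    branch lengths are clamped to zero for display; the pre-clamp values are
    recorded on ``tree.clamped_edges``.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy()
    d = np.asarray(distances, dtype=float)
    g = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(g)]
    labels = [str(x) for x in labels]
    if d.shape != (g, g) or len(labels) != g:
        raise ValidationError("distance matrix and labels are inconsistent")
    if g < 3:
        raise ValidationError("neighbour joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (d < -1e-12).any():
        raise ValidationError("distances must be nonnegative")

    order = np.argsort(labels)
    labels_sorted = [labels[i] for i in order]
    d = d[np.ix_(order, order)].copy()

    clamped: list[tuple[str, float]] = []

    def _attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        if length < 0:
            clamped.append((child.label or "internal", float(length)))
            length = 0.0
        parent.children.append((child, float(length)))
        parent.pre_clamp[id(child)] = float(length)

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels_sorted]
    active = list(range(len(nodes)))
    dist = d

    while len(active) > 3:
        r = len(active)
        sub = dist
        row_sums = sub.sum(1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin is row-major, i.e. the lowest (i, j) pair on ties
        i, j = divmod(int(np.argmin(q)), r)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = TreeNode()
        _attach(parent, nodes[active[i]], li)
        _attach(parent, nodes[active[j]], lj)
        new_dist = 0.5 * (sub[i] + sub[j] - dij)
        keep = [t for t in range(r) if t not in (i, j)]
        next_dist = np.empty((r - 1, r - 1))
        next_dist[: r - 2, : r - 2] = sub[np.ix_(keep, keep)]
        next_dist[: r - 2, r - 2] = new_dist[keep]
        next_dist[r - 2, : r - 2] = new_dist[keep]
        next_dist[r - 2, r - 2] = 0.0
        nodes.append(parent)
        active = [active[t] for t in keep] + [len(nodes) - 1]
        dist = next_dist

    # resolve the final three taxa into a star
    (a, b, c) = active
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    root = TreeNode()
    _attach(root, nodes[a], 0.5 * (dab + dac - dbc))
    _attach(root, nodes[b], 0.5 * (dab + dbc - dac))
    _attach(root, nodes[c], 0.5 * (dac + dbc - dab))

    return PhenoTree(root=root, labels=labels_sorted, clamped_edges=clamped)
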