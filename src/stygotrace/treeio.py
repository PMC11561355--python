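"""Dated binary phylogenies: parsing, validation, ages, and time-slicing.

Trees are time-calibrated (branch lengths in Ma), strictly binary and
ultrametric up to a small relative tolerance; every downstream model in the
package (geographic ranges, habitat traits, character maps) runs on the
:class:`TimeTree` produced here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "Stratification",
    "TreeParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "node_ages",
    "slice_branch_by_strata",
    "prune_tips",
]

#: relative ultrametricity tolerance (fraction of root age)
ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally valid tree violating a model requirement."""


class TimeTree:
    """A rooted, binary, ultrametric, dated tree.

    Nodes are integers ``0 .. n_nodes-1``.  ``parent[i]`` is the parent id
    (``-1`` at the root), ``branch_length[i]`` the length in Ma of the edge
    above node *i* (``nan`` at the root).  Tips carry unique string labels;
    internal nodes may carry an annotation string (e.g. a support value).
    """

    def __init__(
        self,
        parent: np.ndarray,
        branch_length: np.ndarray,
        tip_label: dict[int, str],
        annotation: dict[int, str] | None = None,
        ultrametric_rtol: float = ULTRAMETRIC_RTOL,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.tip_label = dict(tip_label)
        self.annotation = dict(annotation or {})
        self.ultrametric_rtol = float(ultrametric_rtol)
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = self.parent.size
        if n < 3:
            raise TreeValidationError("tree must have at least two tips")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeValidationError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])

        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i == self.root:
                continue
            p = int(self.parent[i])
            if not (0 <= p < n):
                raise TreeValidationError(f"node {i} has out-of-range parent {p}")
            children[p].append(i)
        self.children = [tuple(c) for c in children]

        # acyclicity / single component: walk from root must reach all nodes
        order: list[int] = []
        stack = [self.root]
        seen = np.zeros(n, dtype=bool)
        while stack:
            v = stack.pop()
            if seen[v]:
                raise TreeValidationError("cycle detected in parent map")
            seen[v] = True
            order.append(v)
            stack.extend(self.children[v])
        if not seen.all():
            raise TreeValidationError("tree is not connected to its root")
        self._preorder = np.array(order, dtype=int)
        self._postorder = self._preorder[::-1].copy()

        for i in range(n):
            k = len(self.children[i])
            if k == 0:
                if i not in self.tip_label:
                    raise TreeValidationError(f"tip node {i} has no label")
            elif k != 2:
                raise TreeValidationError(
                    f"internal node {i} has {k} children; trees must be strictly binary"
                )
        labels = list(self.tip_label.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeParseError(f"duplicate tip label: {dup[0]!r}")

        bl = self.branch_length
        for i in range(n):
            if i == self.root:
                continue
            if not np.isfinite(bl[i]) or bl[i] <= 0:
                raise TreeValidationError(
                    f"branch length above node {i} must be finite and > 0, got {bl[i]}"
                )
        self._ages: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tip_ids(self) -> list[int]:
        return sorted(self.tip_label)

    @property
    def n_tips(self) -> int:
        return len(self.tip_label)

    def is_tip(self, i: int) -> bool:
        return len(self.children[i]) == 0

    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents."""
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self._preorder

    @property
    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.branch_length[mask].sum())

    # -- ages --------------------------------------------------------------

    def node_ages(self) -> np.ndarray:
        """Age (Ma before present) of every node; tips clamped to exactly 0.

        Raises :class:`TreeValidationError` if root-to-tip path sums differ
        by more than ``ultrametric_rtol`` relative to the root age.
        """
        if self._ages is not None:
            return self._ages
        depth = np.zeros(self.n_nodes)
        for v in self._preorder:
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.branch_length[v]
        tips = np.array([i for i in range(self.n_nodes) if self.is_tip(i)])
        root_age = float(depth[tips].max())
        dev = float(root_age - depth[tips].min())
        if dev > self.ultrametric_rtol * root_age:
            raise TreeValidationError(
                "tree is not ultrametric: root-to-tip path sums deviate by "
                f"{dev:.6g} Ma (tolerance {self.ultrametric_rtol * root_age:.6g} Ma)"
            )
        ages = root_age - depth
        ages[tips] = 0.0
        self._ages = ages
        return ages

    @property
    def root_age(self) -> float:
        return float(self.node_ages()[self.root])

    # -- Newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TimeTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        """Serialize with 10 significant digits; annotations become node labels."""

        def fmt(i: int) -> str:
            if self.is_tip(i):
                body = self.tip_label[i]
            else:
                kids = ",".join(fmt(c) for c in self.children[i])
                body = f"({kids}){self.annotation.get(i, '')}"
            if i == self.root:
                return body
            return f"{body}:{self.branch_length[i]:.10g}"

        return fmt(self.root) + ";"


def parse_newick(text: str) -> TimeTree:
    """Parse a Newick string into a validated :class:`TimeTree`.

    Requires branch lengths on every non-root edge, a strictly binary
    topology and unique tip labels; internal node labels (support values)
    are preserved as annotations.
    """
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError("unbalanced parentheses: unmatched ')'")
    if depth != 0:
        raise TreeParseError("unbalanced parentheses: unmatched '('")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        msg = str(exc)
        if "Duplicate taxon labels" in msg:
            label = msg.rsplit(":", 1)[-1].strip()
            raise TreeParseError(f"duplicate tip label: {label!r}") from exc
        raise TreeParseError(f"newick parse failed: {msg}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.full(n, np.nan)
    tip_label: dict[int, str] = {}
    annotation: dict[int, str] = {}
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else (nd.label or f"node {i}")
                raise TreeParseError(f"missing branch length at {tok!r}")
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeParseError(f"unlabeled tip (node {i})")
            tip_label[i] = nd.taxon.label
        elif nd.label:
            annotation[i] = str(nd.label)
    return TimeTree(parent, blen, tip_label, annotation)


def write_newick(tree: TimeTree) -> str:
    return tree.to_newick()


def node_ages(tree: TimeTree) -> dict[int, float]:
    """Per-node ages in Ma; see :meth:`TimeTree.node_ages`."""
    ages = tree.node_ages()
    return {int(i): float(a) for i, a in enumerate(ages)}


def prune_tips(tree: TimeTree, keep_labels) -> TimeTree:
    """Subtree induced by a set of tip labels.

    Internal nodes left with a single child are suppressed (their branch
    lengths merge), so the result is again strictly binary and keeps the
    original root-to-tip ages.  At least two tips must be kept.
    """
    keep = set(keep_labels)
    unknown = keep - set(tree.tip_label.values())
    if unknown:
        raise ValueError(f"cannot keep unknown tips: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least two tips to keep")

    kept_below: dict[int, bool] = {}
    for v in tree.postorder():
        v = int(v)
        if tree.is_tip(v):
            kept_below[v] = tree.tip_label[v] in keep
        else:
            kept_below[v] = any(kept_below[c] for c in tree.children[v])

    parent: list[int] = []
    blen: list[float] = []
    labels: dict[int, str] = {}
    annot: dict[int, str] = {}

    def emit(v: int, parent_id: int, extra_len: float) -> None:
        kids = [c for c in tree.children[v] if kept_below[c]]
        if len(kids) == 1:  # unifurcation: merge the child onto this edge
            emit(kids[0], parent_id, extra_len + tree.branch_length[kids[0]])
            return
        my_id = len(parent)
        parent.append(parent_id)
        blen.append(extra_len if parent_id >= 0 else np.nan)
        if not kids:
            labels[my_id] = tree.tip_label[v]
        else:
            if v in tree.annotation:
                annot[my_id] = tree.annotation[v]
            for c in kids:
                emit(c, my_id, float(tree.branch_length[c]))

    # descend to the first node with two kept children (the new crown)
    top = tree.root
    while True:
        kids = [c for c in tree.children[top] if kept_below[c]]
        if len(kids) != 1:
            break
        top = kids[0]
    emit(top, -1, 0.0)
    return TimeTree(np.array(parent), np.array(blen), labels, annot)


@dataclass(frozen=True)
class Stratification:
    """Ordered epoch boundaries, root side first (strictly decreasing, Ma > 0).

    An empty boundary list means a single stratum spanning all time.
    Stratum index 0 is the oldest epoch (ages above the first boundary);
    index ``len(boundary_ages)`` is the youngest (boundary to present).
    """

    boundary_ages: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundary_ages)
        object.__setattr__(self, "boundary_ages", b)
        if any(x <= 0 for x in b):
            raise ValueError("stratum boundaries must be > 0 Ma")
        if any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("stratum boundaries must be strictly decreasing")

    @property
    def n_strata(self) -> int:
        return len(self.boundary_ages) + 1

    def stratum_of(self, age: float) -> int:
        """Stratum index containing a time point; a boundary age belongs to
        the younger stratum."""
        return sum(1 for b in self.boundary_ages if b >= age)

    def check_against_root(self, root_age: float) -> None:
        for b in self.boundary_ages:
            if b >= root_age:
                raise ValueError(
                    f"stratum boundary {b} Ma is not younger than the root age "
                    f"{root_age} Ma"
                )


def slice_branch_by_strata(
    branch: tuple[float, float], strat: Stratification
) -> list[tuple[int, float]]:
    """Split a branch (parent_age, child_age) into per-stratum segments.

    Returns ``[(stratum_index, duration), ...]`` ordered oldest to youngest;
    durations are non-negative and sum exactly to the branch length.
    """
    parent_age, child_age = float(branch[0]), float(branch[1])
    if child_age < 0 or parent_age <= child_age:
        raise ValueError(
            f"need parent_age > child_age >= 0, got ({parent_age}, {child_age})"
        )
    cuts = [parent_age]
    cuts += [b for b in strat.boundary_ages if child_age < b < parent_age]
    cuts.append(child_age)
    out: list[tuple[int, float]] = []
    total = 0.0
    for top, bottom in zip(cuts[:-1], cuts[1:]):
        dur = top - bottom
        if dur < 0:
            raise RuntimeError("internal error: negative segment duration")
        out.append((strat.stratum_of(top), dur))
        total += dur
    # force exact additivity against float noise in the last segment
    drift = (parent_age - child_age) - total
    if out and drift != 0.0:
        idx, d = out[-1]
        out[-1] = (idx, d + drift)
    return out
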