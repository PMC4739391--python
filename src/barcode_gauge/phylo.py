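"""Neighbor-joining trees, newick I/O, and per-species monophyly assessment.

The tree produced by :func:`nj_tree` is unrooted in the usual NJ sense: it is
stored rooted at the junction of the last three lineages, so the "root" node
is a trifurcation and every other internal node is binary.  Monophyly is
therefore assessed on bipartitions (each edge splits the leaves in two), not
on rooted clades, which makes the report independent of where the
trifurcation happens to sit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeNode",
    "Phylogeny",
    "nj_tree",
    "neighbor_joining",
    "monophyly_report",
    "write_newick",
    "read_newick",
]


class TreeNode:
    """A node of a phylogeny. Leaves carry ``name``; edges carry ``length``
    (the length of the branch to the parent; ``raw_length`` keeps the
    pre-clamping NJ estimate for debugging)."""

    __slots__ = ("name", "length", "raw_length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = float(length)
        self.raw_length = float(length)
        self.children: list[TreeNode] = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class Phylogeny:
    """A tree over accessions plus the accession -> species map."""

    root: TreeNode
    species_map: dict[str, str] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distance matrix (order = leaf_names)."""
        names = self.leaf_names
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))
        # distances from each node's leaves accumulate as we unwind recursion
        def below(node):
            # returns {leaf_name: distance from node}
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [below(c) for c in node.children]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for la, da in sub[a].items():
                        for lb, db in sub[b].items():
                            dist = (da + node.children[a].length
                                    + db + node.children[b].length)
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = dist
            merged = {}
            for c, s in zip(node.children, sub):
                for leaf, dist in s.items():
                    merged[leaf] = dist + c.length
            return merged

        below(self.root)
        return names, d


def neighbor_joining(d: np.ndarray, ids: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the lowest (i, j) index pair in
    row-major scan order; negative branch-length estimates are clamped to 0
    with the deficit moved onto the sibling branch.
    """
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes = [TreeNode(name=i) for i in ids]
    if n == 2:
        half = d[0, 1] / 2.0
        for nd in nodes:
            nd.length = nd.raw_length = half
        return TreeNode(children=nodes)
    D = np.array(d, dtype=float)
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima (row-major argmin is exactly that)
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = D[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        ni, nj = nodes[i], nodes[j]
        ni.length = ni.raw_length = li
        nj.length = nj.raw_length = lj
        _clamp_pair(ni, nj)
        parent = TreeNode(children=[ni, nj])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.vstack([D, np.zeros((1, D.shape[1]))])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        k = D.shape[0] - 1
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]
    # join the last three lineages at a trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = node.raw_length = ln
        if node.length < 0:
            node.length = 0.0
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _clamp_pair(ni: TreeNode, nj: TreeNode) -> None:
    """Clamp a negative branch to 0, moving the deficit to the sibling."""
    if ni.length < 0:
        nj.length += ni.length
        ni.length = 0.0
    if nj.length < 0:
        ni.length = max(0.0, ni.length + nj.length)
        nj.length = 0.0


def nj_tree(dm, max_undefined: float = 0.05) -> Phylogeny:
    """Neighbor-joining phylogeny from a distance matrix.

    ``dm`` is a :class:`barcode_gauge.distances.DistanceMatrix` (or anything
    with ``ids``, ``species`` and ``d``).  Undefined (NaN) entries are imputed
    as 1.1 x the maximum defined distance provided they make up at most
    ``max_undefined`` of the off-diagonal entries; more than that is an error.
    """
    d = np.array(dm.d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa for an informative NJ tree")
    off = ~np.eye(n, dtype=bool)
    undef = np.isnan(d) & off
    if undef.any():
        frac = undef.sum() / off.sum()
        if frac > max_undefined:
            raise ValueError(
                f"{frac:.1%} of pairwise distances are undefined "
                f"(saturated); refusing to build a tree")
        d[undef] = np.nanmax(d[off]) * 1.1
    root = neighbor_joining(d, list(dm.ids))
    species = dict(zip(dm.ids, dm.species)) if getattr(dm, "species", None) is not None else {}
    return Phylogeny(root=root, species_map=species)


def monophyly_report(tree: Phylogeny):
    """Per-species monophyly on the (unrooted) NJ tree.

    A species (with >= 2 accessions) is monophyletic when some edge of the
    tree separates exactly its accessions from everything else.  Accessions
    "in the incorrect taxonomic category" are counted by greedy intruder
    removal: repeatedly remove the accession whose removal renders the most
    species monophyletic (ties broken alphabetically), until every species is
    monophyletic among the remaining leaves.  The removed accessions are the
    misplaced ones — a single accession grafted into a foreign clade counts
    once, not against both species involved.

    Returns ``(per_species, total_misplaced)``; ``per_species`` maps each
    assessed species to ``{"n", "misplaced", "monophyletic"}``.
    """
    all_leaves = frozenset(tree.leaf_names)
    sp_of = tree.species_map
    members: dict[str, frozenset] = {}
    tmp: dict[str, set] = {}
    for leaf in all_leaves:
        tmp.setdefault(sp_of.get(leaf, leaf), set()).add(leaf)
    members = {sp: frozenset(m) for sp, m in tmp.items()}

    # one side of every edge, as leaf sets
    clade_sets: list[frozenset] = []
    def collect(node):
        if node.is_leaf:
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(collect(c) for c in node.children))
        clade_sets.append(s)
        return s
    collect(tree.root)

    assessed = sorted(sp for sp, m in members.items() if len(m) >= 2)

    def is_mono(sp, removed):
        mem = members[sp] - removed
        if len(mem) <= 1:
            return True
        keep = all_leaves - removed
        for s in clade_sets:
            side = s & keep
            if side == mem or (keep - side) == mem:
                return True
        return False

    removed: set[str] = set()
    while True:
        broken = [sp for sp in assessed if not is_mono(sp, removed)]
        if not broken:
            break
        candidates = sorted(all_leaves - removed)
        best_leaf, best_gain = None, -1
        for leaf in candidates:
            trial = removed | {leaf}
            gain = sum(is_mono(sp, trial) for sp in broken)
            if gain > best_gain:
                best_leaf, best_gain = leaf, gain
        if best_gain <= 0:
            # no single removal helps; remove one member of the first broken
            # species to guarantee progress
            best_leaf = sorted(members[broken[0]] - removed)[0]
        removed.add(best_leaf)

    report = {}
    for sp in assessed:
        mis = len(members[sp] & removed)
        report[sp] = {
            "n": len(members[sp]),
            "misplaced": mis,
            "monophyletic": mis == 0,
        }
    return report, len(removed)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]':;,]")


def _fmt_label(label: str) -> str:
    if label and _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label or ""


def write_newick(tree: Phylogeny | TreeNode) -> str:
    """Serialize to newick with branch lengths at full (repr) precision."""
    root = tree.root if isinstance(tree, Phylogeny) else tree

    def fmt(node, top=False):
        if node.is_leaf:
            body = _fmt_label(node.name)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _fmt_label(node.name)
        if top:
            return body
        return f"{body}:{float(node.length)!r}"

    return fmt(root, top=True) + ";"


def read_newick(text: str, species_map: dict | None = None) -> Phylogeny:
    """Parse a newick string written by :func:`write_newick` (quoted labels,
    branch lengths); inverse of the writer."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label():
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    raise ValueError("unterminated quoted label")
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_node():
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = parse_label()
            node.name = label or None
        else:
            node.name = parse_label() or None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            node.length = node.raw_length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at offset {pos}")
    if math.isnan(root.length):  # pragma: no cover - defensive
        root.length = 0.0
    return Phylogeny(root=root, species_map=dict(species_map or {}))
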