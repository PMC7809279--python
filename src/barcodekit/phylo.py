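"""Neighbor-joining trees on K2P distances, with nonparametric bootstrap.

The tree builder is the classic Saitou-Nei agglomeration with the
Q-criterion. It is deterministic: Q-matrix ties are broken by the lowest
(row, column) index pair in input label order, and negative branch
lengths are clamped to zero with the deficit transferred to the sibling
branch. On an exactly additive distance matrix NJ recovers the generating
topology and branch lengths.

Bootstrap supports resample alignment columns with replacement, rebuild
the K2P matrix and NJ tree per replicate, and score each internal
bipartition of the original tree by the percentage of replicates that
contain it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .msa_io import Alignment, AlignmentError, complete_deletion
from .distances import DistanceMatrix, distance_matrix


@dataclass
class Node:
    """A rooted representation of the (unrooted) NJ tree.

    The root is the final trifurcation; every other internal node is
    binary. ``support`` is a bootstrap percentage on the edge above the
    node (None on leaves, the root, and before bootstrapping).
    """

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def nj_tree(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining. Requires >= 3 taxa and finite entries."""
    n = dm.n
    if n < 3:
        raise AlignmentError("nj_tree needs at least 3 taxa")
    bad = [
        (dm.labels[i], dm.labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if not np.isfinite(dm.d[i, j])
    ]
    if bad:
        raise AlignmentError(f"non-finite distance cells: {bad}")

    nodes: list[Node] = [Node(name=lab) for lab in dm.labels]
    D = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q criterion; ties broken by lowest (i, j)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = Node(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_d[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation via the three-point formulas
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Node(children=[a, b, c])


def tree_path_lengths(tree: Node) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    dists: dict[tuple[str, str], float] = {}

    def below(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        merged: dict[str, float] = {}
        child_maps = []
        for ch in node.children:
            cm = {k: v + ch.length for k, v in below(ch).items()}
            child_maps.append(cm)
        for x in range(len(child_maps)):
            for y in range(x + 1, len(child_maps)):
                for la, da in child_maps[x].items():
                    for lb, db in child_maps[y].items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
            merged.update(child_maps[x])
        return merged

    below(tree)
    return dists


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: Node) -> dict[frozenset, Node]:
    """Internal-edge bipartitions, keyed by {side, complement} leaf-name sets.

    Only edges splitting the taxa into two groups of >= 2 are internal.
    """
    all_leaves = frozenset(tree.leaf_names())
    out: dict[frozenset, Node] = {}
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out[frozenset([side, other])] = node
    return out


def bootstrap_supports(
    aln: Alignment,
    B: int = 1000,
    seed: int = 0,
    deletion: str = "complete",
) -> tuple[Node, dict[str, float]]:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``B`` times; replicates whose
    distance matrix has saturated/incomparable cells are skipped and
    counted. Returns the annotated original tree and a small diagnostics
    dict (skipped-replicate fraction).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    work = complete_deletion(aln)[0] if deletion == "complete" else aln
    base_dm = distance_matrix(work, deletion="pairwise")
    if base_dm.flagged:
        raise AlignmentError(f"non-finite distance cells: {base_dm.flagged}")
    tree = nj_tree(base_dm)
    target = bipartitions(tree)
    counts = dict.fromkeys(target, 0)

    rng = np.random.default_rng(seed)
    rows = [r.residues for r in work.records]
    mat = np.array([list(s) for s in rows])
    skipped = 0
    used = 0
    for _ in range(B):
        cols = rng.integers(work.length, size=work.length)
        sub = mat[:, cols]
        rep_rows = ["".join(row) for row in sub]
        rep = Alignment(
            work.locus_name,
            tuple(
                type(r)(r.record_id, r.genus, r.species, s)
                for r, s in zip(work.records, rep_rows)
            ),
        )
        try:
            dm = distance_matrix(rep, deletion="pairwise")
            if dm.flagged:
                skipped += 1
                continue
            rep_tree = nj_tree(dm)
        except AlignmentError:
            skipped += 1
            continue
        used += 1
        rep_bi = bipartitions(rep_tree)
        for key in counts:
            if key in rep_bi:
                counts[key] += 1

    if used == 0:
        raise AlignmentError("all bootstrap replicates were saturated")
    for key, node in target.items():
        node.support = 100.0 * counts[key] / used
    diagnostics = {"skipped_fraction": skipped / B, "replicates_used": float(used)}
    return tree, diagnostics


def genus_monophyly(tree: Node, genus_of: dict[str, str]) -> dict[str, bool]:
    """Whether each genus with >= 2 leaves forms a clade in the NJ tree.

    In an unrooted tree a group is monophyletic if one side of some edge
    equals exactly that group (leaf edges included for size-1 groups).
    """
    all_leaves = frozenset(tree.leaf_names())
    sides: set[frozenset] = set()
    for node in tree.walk():
        if node is tree:
            continue
        side = frozenset(node.leaf_names())
        sides.add(side)
        sides.add(all_leaves - side)
    result: dict[str, bool] = {}
    by_genus: dict[str, set[str]] = {}
    for leaf, genus in genus_of.items():
        by_genus.setdefault(genus, set()).add(leaf)
    for genus, members in by_genus.items():
        result[genus] = frozenset(members) in sides or len(members) == 1
    return result


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _fmt_label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Node) -> str:
    """Newick text with branch lengths; bootstrap supports become
    internal-node labels."""

    def fmt(node: Node, top: bool) -> str:
        if node.is_leaf:
            s = _fmt_label(node.name or "")
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            s = f"({inner}){label}"
        if not top:
            s += f":{node.length:g}"
        return s

    return fmt(tree, True) + ";"


def parse_newick(text: str) -> Node:
    """Parse the Newick dialect written by :func:`to_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick text must end with ';'")
    s = text[:-1]
    pos = 0

    def read_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
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

    def read_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(read_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = read_label()
            if label:
                node.support = float(label)
        else:
            node.name = read_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = read_node()
    if pos != len(s):
        raise ValueError(f"trailing Newick text at position {pos}")
    return root
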