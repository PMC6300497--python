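"""Ordination and tree building from a genetic distance matrix.

Two standard views of genetic structure among unique multilocus genotypes:

* principal coordinate analysis (PCoA) — Gower double-centering of the
  squared distances followed by an eigendecomposition; coordinates are
  eigenvectors scaled by the square root of their (positive) eigenvalues.
  Non-Euclidean distance matrices (Bruvo distances generally are) produce
  negative eigenvalues, which are reported but not corrected by default.
* neighbour joining (NJ) — Saitou–Nei agglomeration, consistent on additive
  matrices, with a deterministic lowest-index tie-break and negative branch
  lengths clamped to zero (the deficit moved to the sister edge so the
  cherry's span is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .genotype_io import DistanceMatrix

__all__ = [
    "PcoaResult",
    "TreeNode",
    "pcoa",
    "neighbor_joining",
    "write_newick",
    "tree_distances",
]


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # n x n_positive_axes
    eigenvalues: np.ndarray  # all n, descending (negatives included)
    percent_variance: np.ndarray  # per positive axis, of positive total

    def to_frame(self):
        import pandas as pd

        cols = [f"axis{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, *, correction: str = "none",
         eps: float = 1e-10) -> PcoaResult:
    """Principal coordinate analysis of a distance matrix.

    ``correction`` may be ``"none"`` (default — negative eigenvalues are
    reported as-is), ``"lingoes"`` (adds a constant to the squared
    off-diagonal distances) or ``"cailliez"`` (adds a constant to the
    off-diagonal distances); both corrections make the configuration
    Euclidean-embeddable.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("PCoA needs at least 3 points")
    d = dm.values.copy()
    if correction == "lingoes":
        w = np.linalg.eigvalsh(_gower_center(d))
        c = max(0.0, -w.min())
        if c > eps:
            d2 = d**2 + 2 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
    elif correction == "cailliez":
        delta1 = _gower_center(d)
        a2 = -0.5 * d
        delta2 = a2 - a2.mean(1, keepdims=True) - a2.mean(0, keepdims=True) + a2.mean()
        zero = np.zeros((n, n))
        sp = np.block([[zero, 2 * delta1], [-np.eye(n), -4 * delta2]])
        c = float(np.max(np.linalg.eigvals(sp).real))
        if c > eps:
            d = d + c
            np.fill_diagonal(d, 0.0)
    elif correction != "none":
        raise ValueError("correction must be 'none', 'lingoes' or 'cailliez'")

    b = _gower_center(d)
    vals, vecs = eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(1.0, abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_total = vals[pos].sum()
    pct = 100.0 * vals[pos] / pos_total if pos_total > 0 else np.zeros(pos.sum())
    return PcoaResult(list(dm.ids), coords, vals, pct)


# ---------------------------------------------------------------------------
# Neighbour joining


@dataclass
class TreeNode:
    """Unrooted tree node; ``children`` pairs (child, branch length)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, decimals: int = 6) -> str:
        return self._nwk(decimals) + ";"

    def _nwk(self, decimals: int) -> str:
        if self.is_leaf():
            return _quote(self.name or "")
        inner = ",".join(
            f"{c._nwk(decimals)}:{bl:.{decimals}f}" for c, bl in self.children
        )
        label = _quote(self.name) if self.name else ""
        return f"({inner}){label}"


def _quote(name: str) -> str:
    if any(ch in name for ch in " ():;,'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; returns the trifurcating root node.

    Ties in the Q criterion break deterministically to the lowest index
    pair.  Negative limb lengths are clamped to zero with the deficit moved
    to the sister limb, so the induced distance within each joined cherry is
    unchanged.  Consistent (exact recovery) on additive matrices.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima (argmin is first in row-major order)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = max(0.0, 0.5 * (d[i, k] + d[j, k] - dij))
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def write_newick(tree: TreeNode, path, *, decimals: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(decimals) + "\n")


def tree_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix induced by a tree (sorted leaf names)."""
    # accumulate root-to-leaf paths, then combine via lowest common ancestor
    paths: dict[str, list[tuple[int, float]]] = {}

    def walk(node: TreeNode, path: list[tuple[int, float]]) -> None:
        if node.is_leaf():
            paths[node.name] = list(path)
            return
        for child, bl in node.children:
            walk(child, path + [(id(child), bl)])

    walk(tree, [])
    names = sorted(paths)
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        pi = paths[names[i]]
        for j in range(i + 1, k):
            pj = paths[names[j]]
            shared = 0
            for (ei, _), (ej, _) in zip(pi, pj):
                if ei != ej:
                    break
                shared += 1
            dist = sum(bl for _, bl in pi[shared:]) + sum(bl for _, bl in pj[shared:])
            out[i, j] = out[j, i] = dist
    return names, out
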