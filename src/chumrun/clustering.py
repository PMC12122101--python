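"""Regional similarity of return-rate series: correlation distances + NJ tree.

Distances between two regions u, v are ``d_uv = 1 - r_uv`` with ``r_uv`` the
Pearson correlation of their untransformed return-rate series over the years
both have observed.  The distances are summarized by a classic neighbor-joining
tree (iteratively join the pair minimizing the Q-criterion, standard
three-point branch lengths, negative lengths clamped to zero), which is how
the seven management regions were grouped into four analysis regions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def correlation_distance_matrix(
    rates: pd.DataFrame, min_years: int = 3
) -> pd.DataFrame:
    """Pairwise ``1 - r`` distance matrix between regional return-rate series.

    ``rates`` columns: region, release_year, return_rate.  Each pair uses the
    intersection of its available years (pairwise-complete); fewer than
    ``min_years`` common years, or a zero-variance series on the common years,
    is an error naming the offending pair/region.
    """
    series = {
        reg: g.set_index("release_year")["return_rate"]
        for reg, g in rates.groupby("region")
    }
    labels = sorted(series)
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        u, v = labels[i], labels[j]
        common = series[u].index.intersection(series[v].index)
        if len(common) < min_years:
            raise ValueError(f"{u} vs {v}: only {len(common)} common years")
        a = series[u].loc[common].to_numpy(dtype=float)
        b = series[v].loc[common].to_numpy(dtype=float)
        for name, vec in ((u, a), (v, b)):
            if np.std(vec) == 0:
                raise ValueError(f"zero-variance return-rate series: {name}")
        r = np.corrcoef(a, b)[0, 1]
        D[i, j] = D[j, i] = 1.0 - r
    return pd.DataFrame(D, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJTree:
    """Unrooted tree as an undirected adjacency map with branch lengths."""

    adjacency: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    leaves: tuple[str, ...] = ()

    def _add_edge(self, a: str, b: str, length: float) -> None:
        self.adjacency.setdefault(a, []).append((b, length))
        self.adjacency.setdefault(b, []).append((a, length))

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """Path lengths between all leaves along tree branches."""
        labels = list(self.leaves)
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for src in labels:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, ln in self.adjacency[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + ln
                        stack.append(nbr)
            for dst in labels:
                out.loc[src, dst] = dist[dst]
        return out

    def newick(self, precision: int = 6) -> str:
        """Newick string with branch lengths, rooted at an internal node."""
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[-1] if internal else self.leaves[0]

        def render(node: str, parent: str | None) -> str:
            children = [(c, ln) for c, ln in self.adjacency[node] if c != parent]
            if not children:
                return node.replace(" ", "_")
            parts = [
                f"{render(c, node)}:{ln:.{precision}f}" for c, ln in children
            ]
            label = "" if node not in self.leaves else node.replace(" ", "_")
            return f"({','.join(parts)}){label}"

        return render(root, None) + ";"


def neighbor_joining(d: pd.DataFrame) -> NJTree:
    """Classic neighbor joining (Saitou & Nei) on a distance matrix.

    Iteratively joins the pair (i, j) minimizing
    ``Q(i,j) = (m - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``, assigns limb
    lengths by the standard three-point formulas, and reduces the matrix.
    Ties in Q break by lexicographic label order; negative branch lengths are
    clamped to zero with a logged note.  Requires a symmetric matrix with a
    zero diagonal and at least three labels.
    """
    labels = list(d.index)
    if list(d.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    D = d.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    m = len(labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    tree = NJTree(leaves=tuple(labels))
    active = list(labels)
    dist = {
        (a, b): D[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    next_id = 0

    def dget(a, b):
        return dist[(a, b)]

    while len(active) > 3:
        m = len(active)
        rowsum = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * dget(a, b) - rowsum[a] - rowsum[b]
            if best is None or q < best[0] - 1e-15:
                best = (q, a, b)
        _, a, b = best
        la = 0.5 * dget(a, b) + (rowsum[a] - rowsum[b]) / (2.0 * (m - 2))
        lb = dget(a, b) - la
        la, lb = _clamp(la), _clamp(lb)
        new = f"_nj{next_id}"
        next_id += 1
        tree._add_edge(new, a, la)
        tree._add_edge(new, b, lb)
        for c in active:
            if c in (a, b):
                continue
            dnew = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
            dist[(new, c)] = dist[(c, new)] = dnew
        dist[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    # final three nodes: closed-form three-point lengths
    a, b, c = sorted(active)
    la = 0.5 * (dget(a, b) + dget(a, c) - dget(b, c))
    lb = 0.5 * (dget(a, b) + dget(b, c) - dget(a, c))
    lc = 0.5 * (dget(a, c) + dget(b, c) - dget(a, b))
    center = f"_nj{next_id}"
    tree._add_edge(center, a, _clamp(la))
    tree._add_edge(center, b, _clamp(lb))
    tree._add_edge(center, c, _clamp(lc))
    return tree


def _clamp(length: float) -> float:
    if length < 0:
        logger.info("clamping negative NJ branch length %.4g to 0", length)
        return 0.0
    return length


def tree_splits(tree: NJTree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the leaf set induced by internal edges."""
    leaves = set(tree.leaves)
    splits: set[frozenset[str]] = set()
    seen = set()
    for a in tree.adjacency:
        for b, _ in tree.adjacency[a]:
            if (b, a) in seen:
                continue
            seen.add((a, b))
            # leaves on the 'a' side of edge (a, b)
            side = set()
            stack = [a]
            visited = {b}
            while stack:
                node = stack.pop()
                if node in visited:
                    continue
                visited.add(node)
                if node in leaves:
                    side.add(node)
                for nbr, _ in tree.adjacency[node]:
                    stack.append(nbr)
            if 1 < len(side) < len(leaves) - 1:
                splits.add(frozenset(side))
    return splits
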