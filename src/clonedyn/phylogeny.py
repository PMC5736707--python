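"""Phylogeny enumeration under CCF ordering and sum constraints.

Subclone trees are constrained by the pigeonhole principle on cancer cell
fractions: a parent clone must have CCF at least as large as each progeny
clone in every sample, and the CCFs of sibling clones may not sum above
their parent's CCF (above 1 at the root) at any timepoint.  All parent maps
over the clusters satisfying both rules (within a tolerance ``eps`` on the
noisy point estimates) are enumerated exhaustively; when several trees are
feasible, the one maximizing the summed goodness of fit (R^2) of per-clone
exponential growth models is selected.

A truncal cluster (baseline CCF >= 0.9) roots the tree when present;
otherwise a synthetic germline node with CCF 1 at every timepoint (id 0) is
used as root.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .clustering import CloneCluster
from .kinetics import fit_exponential

GERMLINE_ID = 0
DEFAULT_EPS = 0.02
TRUNCAL_CCF = 0.9


class NoFeasibleTreeError(ValueError):
    pass


@dataclass(frozen=True)
class PhylogenyTree:
    """Parent map over cluster ids; the root maps to ``None``."""

    parent: tuple[tuple[int, int | None], ...]  # sorted (child, parent) pairs
    root: int

    @classmethod
    def from_dict(cls, parent: dict[int, int | None], root: int) -> "PhylogenyTree":
        return cls(parent=tuple(sorted(parent.items())), root=root)

    @property
    def parent_map(self) -> dict[int, int | None]:
        return dict(self.parent)

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent if p == node)

    def depth(self) -> int:
        pm = self.parent_map

        def _d(node: int) -> int:
            p = pm[node]
            return 0 if p is None else 1 + _d(p)

        return max(_d(node) for node in pm)

    def newick(self, labels: dict[int, str] | None = None) -> str:
        labels = labels or {}

        def name(node: int) -> str:
            return labels.get(node, f"C{node}" if node != GERMLINE_ID else "germline")

        def render(node: int) -> str:
            kids = self.children(node)
            if not kids:
                return name(node)
            return "(" + ",".join(render(k) for k in kids) + ")" + name(node)

        return render(self.root) + ";"


def _ccf_map(clusters: list[CloneCluster]) -> dict[int, np.ndarray]:
    return {c.cluster_id: c.ccf_point for c in clusters}


def check_constraints(
    tree: PhylogenyTree, ccf: dict[int, np.ndarray], eps: float = DEFAULT_EPS
) -> bool:
    """Verify ordering (parent >= child - eps) and sibling-sum rules on a tree."""
    pm = tree.parent_map
    n_t = len(next(iter(ccf.values())))
    one = np.ones(n_t)
    get = lambda node: one if node == GERMLINE_ID else ccf[node]
    # acyclicity / single root
    roots = [c for c, p in pm.items() if p is None]
    if roots != [tree.root]:
        return False
    for node in pm:
        seen, cur = set(), node
        while cur is not None:
            if cur in seen:
                return False
            seen.add(cur)
            cur = pm.get(cur)
    for child, parent in pm.items():
        if parent is None:
            continue
        if np.any(get(parent) < get(child) - eps):
            return False
    nodes = set(pm) | {p for p in pm.values() if p is not None}
    for node in nodes:
        kids = [c for c, p in pm.items() if p == node]
        if not kids:
            continue
        sib_sum = np.sum([get(k) for k in kids], axis=0)
        bound = one if node == GERMLINE_ID else get(node)
        if np.any(sib_sum > bound + eps):
            return False
    return True


def feasible_trees(
    clusters: list[CloneCluster], eps: float = DEFAULT_EPS, max_clusters: int = 8
) -> list[PhylogenyTree]:
    """Enumerate all phylogenies consistent with the CCF constraints.

    Exhaustive over parent maps, so limited to ``max_clusters`` clusters.
    Raises :class:`NoFeasibleTreeError` when no tree passes, suggesting a
    larger tolerance.
    """
    if len(clusters) > max_clusters:
        raise ValueError(f"exhaustive enumeration limited to {max_clusters} clusters")
    if not clusters:
        raise ValueError("no clusters to build a tree from")
    ccf = _ccf_map(clusters)
    ids = sorted(ccf)

    truncal = [cid for cid in ids if ccf[cid][0] >= TRUNCAL_CCF]
    if truncal:
        root = max(truncal, key=lambda cid: (ccf[cid][0], -cid))
        free = [cid for cid in ids if cid != root]
        root_parent = None
    else:
        root = GERMLINE_ID
        free = ids
        root_parent = None

    if not free:
        return [PhylogenyTree.from_dict({root: None}, root)]

    # candidate parents per free node, pre-filtered by the ordering rule
    one = np.ones(len(ccf[ids[0]]))
    get = lambda node: one if node == GERMLINE_ID else ccf[node]
    candidates = {
        cid: [
            p
            for p in ([root] + [o for o in free if o != cid])
            if not np.any(get(p) < get(cid) - eps)
        ]
        for cid in free
    }
    trees = []
    for combo in product(*(candidates[cid] for cid in free)):
        pm: dict[int, int | None] = {root: root_parent}
        pm.update(dict(zip(free, combo)))
        tree = PhylogenyTree.from_dict(pm, root)
        if check_constraints(tree, ccf, eps):
            trees.append(tree)
    if not trees:
        raise NoFeasibleTreeError(
            f"no phylogeny satisfies the CCF constraints at eps={eps}; "
            "consider increasing the tolerance"
        )
    return trees


def exclusive_ccf(
    tree: PhylogenyTree, ccf: dict[int, np.ndarray], warn: bool = False
) -> dict[int, np.ndarray]:
    """Clone-exclusive CCF: cluster CCF minus the summed CCF of its children.

    Negative values (constraint slack on noisy estimates) are clipped to 0.
    The synthetic germline root is excluded.
    """
    out = {}
    for cid in ccf:
        kids = [k for k in tree.children(cid) if k != GERMLINE_ID and k in ccf]
        excl = ccf[cid] - (np.sum([ccf[k] for k in kids], axis=0) if kids else 0.0)
        out[cid] = np.clip(excl, 0.0, None)
    return out


def select_tree(
    trees: list[PhylogenyTree],
    clusters: list[CloneCluster],
    days: np.ndarray,
    cell_scale: np.ndarray,
) -> PhylogenyTree:
    """Choose the feasible tree maximizing summed exponential-fit R^2.

    ``cell_scale[t]`` converts a CCF into circulating cells at timepoint t
    (ALC x blood volume x purity).  Each clone's cell count under a topology
    is its exclusive CCF times the scale; clones with fewer than two positive
    counts contribute 0.  Ties prefer the shallowest tree, then the
    lexicographically smallest parent map.
    """
    if len(trees) == 1:
        return trees[0]
    ccf = _ccf_map(clusters)
    days = np.asarray(days, dtype=float)
    scored = []
    for tree in trees:
        excl = exclusive_ccf(tree, ccf)
        total_r2 = 0.0
        for cid, frac in excl.items():
            counts = frac * cell_scale
            fit = fit_exponential(counts, days)
            if fit is not None:
                total_r2 += fit.r2
        scored.append((-total_r2, tree.depth(), tree.parent, tree))
    scored.sort(key=lambda s: s[:3])
    return scored[0][3]


def write_parent_table(tree: PhylogenyTree, path) -> None:
    import pandas as pd

    rows = [{"cluster_id": c, "parent_id": p if p is not None else "."} for c, p in tree.parent]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
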