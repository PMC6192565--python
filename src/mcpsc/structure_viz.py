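"""Distance-matrix construction and structure-space visual analyses.

From a per-pair similarity column a symmetric N x N distance matrix
``D = 1 - S`` (missing -> 1, diagonal 0) is built and fed to:

* metric MDS (SMACOF stress majorization, seeded) for 2-D scatterplots,
* domain- and fold-level heatmaps,
* neighbor-joining trees serialized as Newick and drawn in a circular
  unrooted layout with leaves colored by class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .score_model import ClassificationLabel


@dataclass
class DistanceMatrix:
    """Square symmetric matrix over domains; entries 1 - S in [0, 1]."""

    domains: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.domains)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match domain count")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(self.D) < -1e-12 or np.nanmax(self.D) > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry domain IDs."""

    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.name
        parts = [
            f"{child._newick_inner()}:{length:.10g}" for child, length in self.children
        ]
        return "(" + ",".join(parts) + ")" + self.name


def build_distance_matrix(
    pair_scores: pd.DataFrame,
    column: str,
    domains: Sequence[str] | None = None,
) -> DistanceMatrix:
    """D_ij = 1 - S_ij from a wide per-pair table; missing pairs -> 1.

    Asymmetric leftovers are symmetrized by averaging the two orientations.
    Domains are sorted so downstream tie-breaking is deterministic.
    """
    if column not in pair_scores.columns:
        raise ValueError(f"unknown score column {column!r}")
    if domains is None:
        domains = sorted(set(pair_scores["domain1"]) | set(pair_scores["domain2"]))
    else:
        domains = sorted(domains)
    index = {d: i for i, d in enumerate(domains)}
    n = len(domains)
    S = np.full((n, n), np.nan)
    sub = pair_scores.dropna(subset=[column])
    i = sub["domain1"].map(index).to_numpy()
    j = sub["domain2"].map(index).to_numpy()
    S[i, j] = sub[column].to_numpy(dtype=float)
    # average the two orientations where both exist; copy where one exists
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        S_sym = np.nanmean(np.stack([S, S.T]), axis=0)
    D = 1.0 - S_sym
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    return DistanceMatrix(list(domains), D)


def mds_embed_2d(
    dmat: DistanceMatrix, seed: int = 0, n_init: int = 8, max_iter: int = 5000
) -> tuple[np.ndarray, float]:
    """Metric MDS by SMACOF stress majorization from seeded random starts.

    Returns (N x 2 coordinates, final normalized stress
    ``sqrt(raw_stress / (sum d_ij^2 / 2))``).  Deterministic given seed.
    """
    from sklearn.manifold import MDS

    if len(dmat.domains) < 3:
        raise ValueError("need at least 3 domains to embed")
    mds = MDS(
        n_components=2,
        metric="precomputed",
        metric_mds=True,
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        eps=1e-12,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(dmat.D)
    coords = _polish_stress(coords, dmat.D)
    rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu = np.triu_indices(len(coords), k=1)
    raw_stress = float(((rec[iu] - dmat.D[iu]) ** 2).sum())
    denom = (dmat.D[iu] ** 2).sum()
    stress = float(np.sqrt(raw_stress / denom)) if denom > 0 else 0.0
    return coords, stress


def _polish_stress(coords: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Deterministic local refinement of the raw-stress objective.

    SMACOF's majorization tail converges slowly near the optimum; a short
    quasi-Newton polish pushes exactly-embeddable configurations down to
    numerically zero stress without changing which basin was found.
    """
    from scipy.optimize import minimize

    n, k = coords.shape
    iu = np.triu_indices(n, k=1)

    def objective(flat: np.ndarray):
        X = flat.reshape(n, k)
        diff = X[:, None] - X[None, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        resid = dist[iu] - D[iu]
        val = float((resid ** 2).sum())
        safe = np.where(dist > 0, dist, 1.0)
        coef = np.zeros_like(dist)
        coef[iu] = 2.0 * resid / safe[iu]
        coef = coef + coef.T
        grad = (coef[:, :, None] * diff).sum(axis=1)
        return val, grad.ravel()

    res = minimize(objective, coords.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-18, "gtol": 1e-12})
    out = res.x.reshape(n, k)
    return out if res.fun <= objective(coords.ravel())[0] else coords


def fold_aggregate_matrix(
    dmat: DistanceMatrix,
    labels: Mapping[str, ClassificationLabel],
    level: int = 2,
) -> tuple[list[str], np.ndarray]:
    """Group x group mean distances at a label level (default 2 = fold).

    Diagonal entries average within-group pairs (i != j); a singleton group
    has no such pair and gets 0 by convention.
    """
    groups = sorted({".".join(labels[d].levels[:level]) for d in dmat.domains})
    gidx = {g: k for k, g in enumerate(groups)}
    member = np.array([gidx[".".join(labels[d].levels[:level])] for d in dmat.domains])
    ng = len(groups)
    out = np.zeros((ng, ng))
    for a in range(ng):
        for b in range(ng):
            ia = np.where(member == a)[0]
            ib = np.where(member == b)[0]
            block = dmat.D[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    out[a, b] = 0.0  # singleton group, flagged by convention
                    continue
                mask = ~np.eye(len(ia), dtype=bool)
                out[a, b] = float(block[mask].mean())
            else:
                out[a, b] = float(block.mean())
    return groups, out


def nj_tree(dmat: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining (Saitou-Nei) agglomeration.

    Exact on additive distances; ties in the Q criterion break to the
    smallest (i, j) index pair; negative branch lengths are clamped to 0.
    Returns the unrooted tree represented with a trifurcating root.
    """
    D = dmat.D.astype(float).copy()
    if not np.isfinite(D).all():
        raise ValueError("distances must be finite")
    n = len(dmat.domains)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=d) for d in dmat.domains]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n
    edges: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    def d(a: int, b: int) -> float:
        return dist[(a, b)] if a <= b else dist[(b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for x in range(m):
            for y in range(x + 1, m):
                a, b = active[x], active[y]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = TreeNode()
        new.children = [(edges[a], la), (edges[b], lb)]
        for c in active:
            if c in (a, b):
                continue
            dist[(min(c, next_id), max(c, next_id))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        edges[next_id] = new
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = TreeNode()
    root.children = [
        (edges[a], max(la, 0.0)),
        (edges[b], max(lb, 0.0)),
        (edges[c], max(lc, 0.0)),
    ]
    return root


def tree_path_lengths(root: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a tree (for additivity checks)."""
    # collect leaf distances bottom-up: map leaf -> distance to current node
    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        sub = []
        for child, length in node.children:
            dd = walk(child)
            sub.append({k: v + length for k, v in dd.items()})
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for u, du in sub[i].items():
                    for v, dv in sub[j].items():
                        key = (u, v) if u < v else (v, u)
                        paths[key] = du + dv
        merged: dict[str, float] = {}
        for s in sub:
            merged.update(s)
        return merged

    paths: dict[tuple[str, str], float] = {}
    walk(root)
    return paths


def _class_colors(labels: Mapping[str, ClassificationLabel]) -> dict[str, str]:
    import matplotlib.pyplot as plt

    classes = sorted({lab.levels[0] for lab in labels.values()})
    cmap = plt.get_cmap("tab10")
    return {c: cmap(i % 10) for i, c in enumerate(classes)}


def heatmap_render(
    matrix: np.ndarray,
    names: Sequence[str],
    path: str | Path,
    title: str = "",
) -> None:
    """Label-ordered heatmap of a square distance matrix, written to file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    show_ticks = len(names) <= 40
    fig, ax = plt.subplots(figsize=(8, 7))
    sns.heatmap(
        pd.DataFrame(matrix, index=list(names), columns=list(names)),
        ax=ax,
        cmap="viridis_r",
        xticklabels=show_ticks,
        yticklabels=show_ticks,
        square=True,
    )
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mds_scatter_render(
    coords: np.ndarray,
    domains: Sequence[str],
    labels: Mapping[str, ClassificationLabel],
    path: str | Path,
    title: str = "",
) -> None:
    """2-D MDS scatterplot colored by class (level 1), with legend."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = _class_colors(labels)
    fig, ax = plt.subplots(figsize=(7, 6))
    for cls in sorted(colors):
        idx = [i for i, d in enumerate(domains) if labels[d].levels[0] == cls]
        ax.scatter(
            coords[idx, 0], coords[idx, 1], s=18, color=colors[cls], label=f"class {cls}"
        )
    ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tree_render(
    root: TreeNode,
    labels: Mapping[str, ClassificationLabel],
    path: str | Path,
    title: str = "",
) -> None:
    """Circular unrooted tree layout with leaves colored by class."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    leaves = root.leaves()
    n = len(leaves)
    angle = {leaf: 2 * np.pi * i / n for i, leaf in enumerate(leaves)}

    # equal-angle radial layout: radius = cumulative depth (unit branch steps)
    pos: dict[int, tuple[float, float]] = {}
    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    leaf_xy: dict[str, tuple[float, float]] = {}

    def depth(node: TreeNode) -> int:
        if node.is_leaf():
            return 0
        return 1 + max(depth(c) for c, _ in node.children)

    max_depth = depth(root)

    def place(node: TreeNode, level: int) -> float:
        # returns the mean angle of the subtree; records positions
        if node.is_leaf():
            th = angle[node.name]
            r = 1.0
            xy = (r * np.cos(th), r * np.sin(th))
            leaf_xy[node.name] = xy
            pos[id(node)] = xy
            return th
        child_angles = [place(child, level + 1) for child, _ in node.children]
        th = float(np.mean(child_angles))
        r = level / (max_depth + 1)
        xy = (r * np.cos(th), r * np.sin(th))
        pos[id(node)] = xy
        for child, _ in node.children:
            segments.append((xy, pos[id(child)]))
        return th

    place(root, 0)
    colors = _class_colors(labels)
    fig, ax = plt.subplots(figsize=(7, 7))
    for (x1, y1), (x2, y2) in segments:
        ax.plot([x1, x2], [y1, y2], color="0.6", lw=0.8, zorder=1)
    seen: set[str] = set()
    for leaf, (x, y) in leaf_xy.items():
        cls = labels[leaf].levels[0]
        label = f"class {cls}" if cls not in seen else None
        seen.add(cls)
        ax.scatter([x], [y], s=20, color=colors[cls], label=label, zorder=2)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
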