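"""Per-node embedded random forests and depth variable importance.

At each node of the overall classification tree a small random forest of
"embedded" trees is grown on resamples of the node's rows, solely to rank
the candidate split variables.  For each embedded tree T and covariate j
the depth importance score is

    score(T, j) = sum over nodes t of T split by j of 2^(-L(t)) * G_t,

where L(t) is the depth of node t (root depth 1) and G_t the split
criterion at t.  The score rewards strong splits close to the root; the
covariate with the largest score summed over the forest is chosen to split
the overall node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import ClinicalDataset
from .split_criteria import best_split_for_variable, outcome_degenerate

__all__ = [
    "ForestParams",
    "EmbeddedNode",
    "EmbeddedTree",
    "depth_weight",
    "tree_variable_score",
    "grow_embedded_tree",
    "select_best_variable",
]


@dataclass
class ForestParams:
    """Tuning knobs of the embedded forests.

    ``mtry`` and ``nmin2`` default to ceil(sqrt(p)) and max(5, nmin // 2)
    and are resolved by :func:`resolve_forest_params` before growth.
    ``resample=False`` disables the bootstrap (a test hook: with
    ``ntree=1, mtry=p`` the embedded root split then equals the global
    exhaustive-search best split).
    """

    ntree: int = 50
    mtry: Optional[int] = None
    maxdepth2: int = 6
    nmin2: Optional[int] = None
    resample: bool = True

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nmin2 is not None and self.nmin2 < 2:
            raise ValueError("nmin2 must be >= 2")


def resolve_forest_params(params: ForestParams, p: int, nmin: int) -> ForestParams:
    """Fill defaulted fields given the covariate count and overall nmin."""
    mtry = params.mtry if params.mtry is not None else max(1, math.ceil(math.sqrt(p)))
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry={mtry} outside 1..{p}")
    nmin2 = params.nmin2 if params.nmin2 is not None else max(5, nmin // 2)
    return ForestParams(ntree=params.ntree, mtry=mtry, maxdepth2=params.maxdepth2,
                        nmin2=nmin2, resample=params.resample)


@dataclass
class EmbeddedNode:
    depth: int
    size: int
    variable: Optional[str] = None
    g: float = 0.0
    left: Optional["EmbeddedNode"] = None
    right: Optional["EmbeddedNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class EmbeddedTree:
    root: EmbeddedNode
    nodes: list = field(default_factory=list)  # preorder

    def internal_nodes(self):
        return [n for n in self.nodes if not n.is_leaf]


def depth_weight(L: int) -> float:
    """2^(-L); the root has depth 1 and weight 1/2."""
    if L < 1:
        raise ValueError("node depth starts at 1")
    return 2.0 ** (-L)


def tree_variable_score(tree: EmbeddedTree, j: str) -> float:
    """Depth importance of covariate j in one tree: sum of 2^(-L) * G over
    the nodes split by j (0 when j splits no node)."""
    return sum(depth_weight(n.depth) * n.g
               for n in tree.nodes if n.variable == j)


def grow_embedded_tree(
    dataset: ClinicalDataset,
    rows: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
) -> EmbeddedTree:
    """Grow one embedded tree on a bootstrap resample of the node's rows.

    Greedy growth: at each embedded node, ``mtry`` covariates are sampled
    without replacement and the admissible candidate split with the largest
    criterion is taken.  Growth stops at ``maxdepth2``, below ``2 * nmin2``
    rows, with fewer than two arms, or with no admissible split.
    Deterministic given the generator state.
    """
    if params.mtry is None or params.nmin2 is None:
        raise ValueError("ForestParams must be resolved before growth")
    names = dataset.covariate_names
    sample = rng.choice(rows, size=len(rows), replace=True) if params.resample else np.asarray(rows)
    nodes: list = []

    def grow(node_rows: np.ndarray, depth: int) -> EmbeddedNode:
        node = EmbeddedNode(depth=depth, size=len(node_rows))
        nodes.append(node)
        if (depth >= params.maxdepth2
                or len(node_rows) < 2 * params.nmin2
                or len(np.unique(dataset.treatment[node_rows])) < 2
                or outcome_degenerate(dataset, node_rows)):
            return node
        k = min(params.mtry, len(names))
        cand_idx = sorted(rng.choice(len(names), size=k, replace=False))
        best = None
        for i in cand_idx:  # ascending index: ties keep the earlier covariate
            split = best_split_for_variable(dataset, node_rows, names[i],
                                            min_child=params.nmin2)
            if split is not None and (best is None
                                      or split.criterion.g > best.criterion.g):
                best = split
        if best is None:
            return node
        z = best.left_mask(dataset, node_rows)
        node.variable = best.variable
        node.g = best.criterion.g
        node.left = grow(node_rows[z], depth + 1)
        node.right = grow(node_rows[~z], depth + 1)
        return node

    root = grow(np.asarray(sample), 1)
    return EmbeddedTree(root=root, nodes=nodes)


def _tree_seed(seed_seq: np.random.SeedSequence, i: int) -> np.random.SeedSequence:
    # counter-derived child stream: tree i's stream does not depend on ntree
    return np.random.SeedSequence(entropy=seed_seq.entropy,
                                  spawn_key=seed_seq.spawn_key + (i,))


def select_best_variable(
    dataset: ClinicalDataset,
    rows: np.ndarray,
    params: ForestParams,
    seed_seq: np.random.SeedSequence,
):
    """Grow the embedded forest of a node and pick the covariate with the
    largest accumulated depth importance.

    Returns ``(name, scores)``; ``name`` is ``None`` when every score is
    zero (no informative variable — the caller makes the node terminal).
    Ties go to the covariate earliest in column order.
    """
    names = dataset.covariate_names
    scores = {name: 0.0 for name in names}
    for i in range(params.ntree):
        rng = np.random.default_rng(_tree_seed(seed_seq, i))
        tree = grow_embedded_tree(dataset, rows, params, rng)
        for node in tree.nodes:
            if node.variable is not None:
                scores[node.variable] += depth_weight(node.depth) * node.g
    best, best_val = None, 0.0
    for name in names:
        if scores[name] > best_val:
            best, best_val = name, scores[name]
    return best, scores
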