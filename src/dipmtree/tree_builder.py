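"""Overall classification-tree growth for treatment-subgroup discovery.

Two builders share the same recursion and differ only in how a node picks
its split variable:

* :func:`build_dipm_tree` — at each node an embedded random forest ranks
  the covariates by depth variable importance and the best split of the
  winning covariate is taken (the DIPM method);
* :func:`build_spm_tree` — the classical exhaustive search: the single
  admissible split with the largest criterion over all covariates wins.

Nodes are recorded in level order with 1-based ids; the root has depth 1.
Every node, internal or terminal, carries its optimal treatment label
(largest within-node mean response, or largest restricted mean survival
time) and the per-arm summaries behind it.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import ClinicalDataset, Split
from .embedded_forest import ForestParams, resolve_forest_params, select_best_variable
from .split_criteria import (
    best_split_for_variable,
    node_arm_summary,
    outcome_degenerate,
)

__all__ = [
    "TreeParams",
    "TreeNode",
    "Tree",
    "stopping_rule",
    "best_split_of_variable",
    "build_dipm_tree",
    "build_spm_tree",
]

logger = logging.getLogger(__name__)


@dataclass
class TreeParams:
    """Growth controls of the overall tree."""

    method: str = "dipm"
    nmin: int = 20
    maxdepth: int = 4
    forest: ForestParams = field(default_factory=ForestParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("dipm", "spm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.nmin < 4:
            raise ValueError("nmin must be >= 4")
        if self.maxdepth < 1:
            raise ValueError("maxdepth must be >= 1")


@dataclass
class TreeNode:
    """One record of the overall tree (level-order id, root id 1)."""

    id: int
    depth: int
    size: int
    rows: Optional[np.ndarray] = None
    split: Optional[Split] = None
    lchild: Optional[int] = None
    rchild: Optional[int] = None
    g: Optional[float] = None
    besttrt: object = None
    arm_summary: Optional[dict] = None
    terminal: bool = True
    var_scores: Optional[dict] = None


@dataclass
class Tree:
    """An overall tree: node records plus the metadata prediction needs."""

    nodes: list
    outcome_kind: str
    arm_labels: list
    method: str
    response_name: str = "Y"
    treatment_name: str = "treatment"
    status_name: Optional[str] = None
    category_universe: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n.id: n for n in self.nodes}
        if len(self._index) != len(self.nodes):
            raise ValueError("node ids must be unique")

    def reindex(self) -> None:
        self._index = {n.id: n for n in self.nodes}

    def node(self, node_id: int) -> TreeNode:
        return self._index[node_id]

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    def leaves(self) -> list:
        return [n for n in self.nodes if n.terminal]

    def split_variables(self) -> list:
        seen = []
        for n in self.nodes:
            if n.split is not None and n.split.variable not in seen:
                seen.append(n.split.variable)
        return seen


def stopping_rule(dataset: ClinicalDataset, rows: np.ndarray, depth: int,
                  params: TreeParams) -> bool:
    """True when a node must be terminal: too few rows, at the depth cap,
    fewer than two arms present, or a degenerate outcome."""
    if len(rows) < params.nmin or depth >= params.maxdepth:
        return True
    if len(np.unique(dataset.treatment[rows])) < 2:
        return True
    return outcome_degenerate(dataset, rows)


def best_split_of_variable(dataset: ClinicalDataset, rows: np.ndarray,
                           name: str) -> Optional[Split]:
    """Best admissible split of one covariate in an overall-tree node."""
    return best_split_for_variable(dataset, rows, name, min_child=1)


def _exhaustive_best_split(dataset: ClinicalDataset, rows: np.ndarray) -> Optional[Split]:
    best = None
    for name in dataset.covariate_names:  # column order breaks ties
        split = best_split_of_variable(dataset, rows, name)
        if split is not None and (best is None
                                  or split.criterion.g > best.criterion.g):
            best = split
    return best


def _build(dataset: ClinicalDataset, params: TreeParams, use_forest: bool,
           seed: Optional[int]) -> Tree:
    dataset = _require_validated(dataset)
    if seed is None:
        seed = params.seed
    forest = resolve_forest_params(params.forest, len(dataset.covariate_names),
                                   params.nmin)
    nodes = []
    next_id = 2
    queue = deque([(1, dataset.all_rows(), 1)])  # (id, rows, depth)
    while queue:
        node_id, rows, depth = queue.popleft()
        summary = node_arm_summary(dataset, rows)
        best_code = max(sorted(summary), key=lambda c: (summary[c], -c))
        node = TreeNode(
            id=node_id, depth=depth, size=len(rows), rows=rows,
            besttrt=dataset.arm_label(best_code),
            arm_summary={str(dataset.arm_label(c)): v for c, v in summary.items()},
        )
        nodes.append(node)
        if not stopping_rule(dataset, rows, depth, params):
            split = None
            if use_forest:
                seq = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                             spawn_key=(int(node_id),))
                var, scores = select_best_variable(dataset, rows, forest, seq)
                node.var_scores = scores
                if var is not None:
                    split = best_split_of_variable(dataset, rows, var)
            else:
                split = _exhaustive_best_split(dataset, rows)
            if split is not None:
                z = split.left_mask(dataset, rows)
                node.split = split
                node.g = split.criterion.g
                node.terminal = False
                node.lchild, node.rchild = next_id, next_id + 1
                queue.append((next_id, rows[z], depth + 1))
                queue.append((next_id + 1, rows[~z], depth + 1))
                next_id += 2
                logger.info("node %d (n=%d, depth %d): split %s, G=%.4g",
                            node_id, len(rows), depth, split.describe(),
                            split.criterion.g)
    universe = {name: tuple(str(v) for v in labels)
                for name, labels in dataset.category_labels.items()}
    return Tree(
        nodes=nodes,
        outcome_kind=dataset.outcome_kind,
        arm_labels=list(dataset.arm_labels),
        method="dipm" if use_forest else "spm",
        response_name=dataset.response_name,
        treatment_name=dataset.treatment_name,
        status_name=dataset.status_name,
        category_universe=universe,
    )


def _require_validated(dataset) -> ClinicalDataset:
    if not isinstance(dataset, ClinicalDataset):
        raise TypeError("expected a validated ClinicalDataset; "
                        "run validate_dataset / read_clinical_table first")
    return dataset


def build_dipm_tree(dataset: ClinicalDataset, params: Optional[TreeParams] = None,
                    seed: Optional[int] = None) -> Tree:
    """Grow the forest-guided tree; deterministic given (dataset, params, seed)."""
    params = params or TreeParams()
    return _build(dataset, params, use_forest=True, seed=seed)


def build_spm_tree(dataset: ClinicalDataset, params: Optional[TreeParams] = None) -> Tree:
    """Grow the exhaustive-split tree (no forest, no randomness)."""
    params = params or TreeParams(method="spm")
    return _build(dataset, params, use_forest=False, seed=0)
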