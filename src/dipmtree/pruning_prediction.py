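"""Same-treatment pruning and per-subject optimal-treatment prediction.

A split whose two terminal children recommend the same arm carries no
decision value; pruning repeatedly collapses such sibling pairs into their
parent until none remain.  Prediction routes each subject from the root to
a leaf through the stored split rules and reports the leaf's optimal
treatment.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .tree_builder import Tree, TreeNode

__all__ = [
    "TreatmentRecommendation",
    "prune_same_treatment",
    "assign_leaf",
    "predict_optimal_treatment",
]

logger = logging.getLogger(__name__)


@dataclass
class TreatmentRecommendation:
    """Per-subject output: assigned leaf, recommended arm, and the leaf's
    per-arm outcome summaries (mean response or restricted mean survival
    time) when the tree carries them."""

    row: int
    leaf: int
    arm: object
    arm_summary: Optional[dict] = None


def prune_same_treatment(tree: Tree) -> Tree:
    """Collapse terminal sibling pairs sharing an optimal treatment.

    Applies the merge deepest-first (then smallest parent id) and iterates
    to a fixed point, so a merge that creates a new same-label sibling pair
    is itself merged.  Surviving nodes keep their id, membership, label and
    split.  The input tree is not modified.
    """
    tree = copy.deepcopy(tree)
    while True:
        candidates = []
        for node in tree.nodes:
            if node.terminal:
                continue
            left, right = tree.node(node.lchild), tree.node(node.rchild)
            if left.terminal and right.terminal and left.besttrt == right.besttrt:
                candidates.append(node)
        if not candidates:
            break
        node = min(candidates, key=lambda n: (-n.depth, n.id))
        label = tree.node(node.lchild).besttrt
        logger.info("pruning node %d: children %d/%d both recommend %s",
                    node.id, node.lchild, node.rchild, label)
        drop = {node.lchild, node.rchild}
        node.terminal = True
        node.split = None
        node.g = None
        node.lchild = node.rchild = None
        node.besttrt = label
        tree.nodes = [n for n in tree.nodes if n.id not in drop]
        tree.reindex()
    return tree


def _route(tree: Tree, node: TreeNode, row: Mapping) -> TreeNode:
    while not node.terminal:
        split = node.split
        value = row[split.variable]
        if split.var_type == "nominal":
            universe = tree.category_universe.get(split.variable)
            sval = str(value)
            if universe is not None and sval not in universe:
                logger.warning("unseen category %r for %s: routing right",
                               value, split.variable)
            go_left = sval in split.subset
        else:
            go_left = float(value) <= split.cutpoint
        node = tree.node(node.lchild if go_left else node.rchild)
    return node


def assign_leaf(tree: Tree, row: Mapping) -> int:
    """Leaf id for one covariate row (values at a cutpoint go left)."""
    return _route(tree, tree.root, row).id


def predict_optimal_treatment(tree: Tree, table) -> pd.DataFrame:
    """Recommend a treatment for every row of ``table``.

    Returns a frame with columns ``row`` (positional index), ``leaf``,
    ``recommended``, and one ``summary_<arm>`` column per arm seen in the
    tree's leaf summaries.  Raises if a split variable is missing.
    """
    df = pd.DataFrame(table)
    needed = tree.split_variables()
    missing = [v for v in needed if v not in df.columns]
    if missing:
        raise ValueError(f"prediction table lacks split variable(s): {missing}")

    arms = [str(a) for a in tree.arm_labels]
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        leaf = _route(tree, tree.root, row)
        rec = {"row": i, "leaf": leaf.id, "recommended": leaf.besttrt}
        summary = leaf.arm_summary or {}
        for a in arms:
            rec[f"summary_{a}"] = summary.get(a, np.nan)
        records.append(rec)
    return pd.DataFrame.from_records(records)
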