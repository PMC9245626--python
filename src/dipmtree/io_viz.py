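"""Readers, writers, tree serialization, render exports, and the CLI.

The model is specified with the textual convention
``Y ~ treatment | X1 + X2`` for continuous outcomes and
``Surv(Y, delta) ~ treatment | X1 + X2`` for survival outcomes; the
wildcard form ``Y ~ treatment | .`` uses every remaining column as a
candidate split variable.  Trees are serialized as one-row-per-node CSV
tables and can be exported as Graphviz dot text or JSON with per-leaf
treatment-group summaries (quartiles of the response, or Kaplan-Meier
curves and restricted mean survival times).
"""

from __future__ import annotations

import csv
import json
import logging
import re
import sys
from dataclasses import dataclass
from typing import Optional, Sequence

import click
import numpy as np
import pandas as pd

from .data_model import ClinicalDataset, Split, parse_types, validate_dataset
from .embedded_forest import ForestParams
from .pruning_prediction import predict_optimal_treatment, prune_same_treatment
from .split_criteria import km_estimate, restricted_mean_survival_time
from .tree_builder import Tree, TreeNode, TreeParams, build_dipm_tree, build_spm_tree
from . import synthetic_data

__all__ = [
    "ModelSpec",
    "parse_model_spec",
    "read_clinical_table",
    "write_tree_table",
    "read_tree_table",
    "export_tree_render",
    "leaf_summaries",
    "km_estimate",
    "cli_main",
]

logger = logging.getLogger(__name__)

_TABLE_COLUMNS = ["node", "depth", "nsubj", "splitvar", "vartype", "splitval",
                  "lchild", "rchild", "G", "besttrt", "terminal"]


@dataclass(frozen=True)
class ModelSpec:
    """Parsed model-role convention."""

    response: str
    treatment: str
    status: Optional[str] = None
    covariates: Optional[tuple] = None  # None = wildcard "."

    @property
    def outcome_kind(self) -> str:
        return "survival" if self.status else "continuous"


_MODEL_RE = re.compile(
    r"^\s*(?:Surv\(\s*([^\s,()]+)\s*,\s*([^\s,()]+)\s*\)|([^\s~|]+))"
    r"\s*~\s*([^\s|]+)\s*\|\s*(.+?)\s*$"
)


def parse_model_spec(text: str) -> ModelSpec:
    """Parse ``Y ~ treatment | X1 + X2`` / ``Surv(Y, d) ~ treatment | .``."""
    m = _MODEL_RE.match(text)
    if not m:
        raise ValueError(f"malformed model specification: {text!r}")
    surv_y, surv_d, cont_y, treatment, rhs = m.groups()
    response = surv_y if surv_y else cont_y
    status = surv_d
    if rhs.strip() == ".":
        covariates = None
    else:
        covariates = tuple(v.strip() for v in rhs.split("+"))
        if any(not v or " " in v for v in covariates):
            raise ValueError(f"malformed covariate list in model: {rhs!r}")
    names = [response, treatment] + ([status] if status else []) \
        + list(covariates or ())
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate column names in model: {text!r}")
    return ModelSpec(response=response, treatment=treatment, status=status,
                     covariates=covariates)


def _check_header(df: pd.DataFrame) -> None:
    for col in df.columns:
        try:
            float(str(col))
        except ValueError:
            continue
        raise ValueError("table appears to lack a header row "
                         f"(numeric column name {col!r})")


def read_clinical_table(path, spec=None, types: Optional[Sequence[str]] = None,
                        response: Optional[str] = None,
                        treatment: Optional[str] = None,
                        status: Optional[str] = None) -> ClinicalDataset:
    """Read a CSV table and validate it into a :class:`ClinicalDataset`.

    Role assignment comes from a model spec (text or :class:`ModelSpec`),
    from an ordered ``types`` list covering every column, or from explicit
    response/treatment/status names (remaining columns default to ordinal).
    """
    df = pd.read_csv(path)
    _check_header(df)
    if isinstance(spec, str):
        spec = parse_model_spec(spec)
    if spec is not None:
        response, treatment, status = spec.response, spec.treatment, spec.status
        outcome_kind = spec.outcome_kind
        if types is not None:
            roles = parse_types(types, df.columns, outcome_kind)
        else:
            keep = spec.covariates
            roles = {}
            for col in df.columns:
                if col == response:
                    roles[col] = "response"
                elif col == treatment:
                    roles[col] = "treatment"
                elif status and col == status:
                    roles[col] = "status"
                elif keep is None or col in keep:
                    roles[col] = "ordinal"
            missing = [c for c in (keep or ()) if c not in roles]
            if missing:
                raise ValueError(f"model names absent from table: {missing}")
            for col in (response, treatment) + ((status,) if status else ()):
                if col not in df.columns:
                    raise ValueError(f"model column {col!r} absent from table")
    elif types is not None:
        outcome_kind = "survival" if "status" in list(types) else "continuous"
        roles = parse_types(types, df.columns, outcome_kind)
    else:
        outcome_kind = "survival" if status else "continuous"
        roles = parse_types(None, df.columns, outcome_kind,
                            response=response, treatment=treatment, status=status)
    return validate_dataset(df[list(roles)], roles)


# ---------------------------------------------------------------------------
# tree table serialization


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{float(x):.17g}"


def write_tree_table(tree: Tree, path) -> None:
    """Write the node table as CSV (one row per node, level-order ids)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TABLE_COLUMNS)
        for n in tree.nodes:
            if n.split is None:
                splitvar = vartype = splitval = ""
            else:
                splitvar = n.split.variable
                vartype = n.split.var_type
                if n.split.var_type == "nominal":
                    splitval = "{" + ",".join(n.split.subset) + "}"
                else:
                    splitval = _fmt(n.split.cutpoint)
            w.writerow([
                n.id, n.depth, n.size, splitvar, vartype, splitval,
                "" if n.lchild is None else n.lchild,
                "" if n.rchild is None else n.rchild,
                _fmt(n.g), str(n.besttrt), int(n.terminal),
            ])


def read_tree_table(path) -> Tree:
    """Rebuild a routable tree from its CSV node table.

    Memberships and per-arm summaries are not stored in the table, so the
    result supports prediction and re-serialization but not re-rendering.
    """
    nodes = []
    arm_labels = []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != _TABLE_COLUMNS:
            raise ValueError(f"unexpected tree table header: {header}")
        for rec in r:
            (nid, depth, nsubj, splitvar, vartype, splitval,
             lchild, rchild, g, besttrt, terminal) = rec
            split = None
            if splitvar:
                if vartype == "nominal":
                    subset = tuple(splitval.strip("{}").split(","))
                    split = Split(splitvar, vartype, subset=subset)
                else:
                    split = Split(splitvar, vartype, cutpoint=float(splitval))
            nodes.append(TreeNode(
                id=int(nid), depth=int(depth), size=int(nsubj), split=split,
                lchild=int(lchild) if lchild else None,
                rchild=int(rchild) if rchild else None,
                g=float(g) if g else None, besttrt=besttrt,
                terminal=bool(int(terminal)),
            ))
            if besttrt not in arm_labels:
                arm_labels.append(besttrt)
    return Tree(nodes=nodes, outcome_kind="unknown", arm_labels=arm_labels,
                method="unknown")


# ---------------------------------------------------------------------------
# renders


def leaf_summaries(tree: Tree, dataset: ClinicalDataset) -> dict:
    """Per-leaf, per-arm outcome summaries for plotting.

    Continuous: n and quartiles of Y.  Survival: n, the Kaplan-Meier step
    curve and the restricted mean survival time at the leaf's largest
    observed time.  Requires a freshly fitted tree (with memberships).
    """
    out = {}
    for leaf in tree.leaves():
        if leaf.rows is None:
            raise ValueError("leaf summaries need a fitted tree with memberships")
        rows = leaf.rows
        arm = dataset.treatment[rows]
        per_arm = {}
        for code in np.unique(arm):
            sel = rows[arm == code]
            label = str(dataset.arm_label(code))
            y = dataset.y[sel]
            if dataset.outcome_kind == "continuous":
                q1, med, q3 = np.percentile(y, [25, 50, 75])
                per_arm[label] = {"n": int(len(sel)), "mean": float(y.mean()),
                                  "q1": float(q1), "median": float(med),
                                  "q3": float(q3)}
            else:
                d = dataset.delta[sel]
                t, s = km_estimate(y, d)
                tau = float(dataset.y[rows].max())
                per_arm[label] = {
                    "n": int(len(sel)),
                    "rmst": restricted_mean_survival_time(y, d, tau),
                    "km_time": [float(v) for v in t],
                    "km_survival": [float(v) for v in s],
                }
        out[leaf.id] = per_arm
    return out


def _dot_escape(s: str) -> str:
    return s.replace('"', r'\"')


def export_tree_render(tree: Tree, dataset: ClinicalDataset, path,
                       fmt: str = "dot") -> None:
    """Export a plot-ready tree description: Graphviz ``dot`` text or a
    ``json`` document embedding the numeric leaf summaries."""
    summaries = leaf_summaries(tree, dataset)
    if fmt == "dot":
        lines = ["digraph tree {", '  node [shape=box];']
        for n in tree.nodes:
            if n.terminal:
                per_arm = summaries[n.id]
                if dataset.outcome_kind == "continuous":
                    body = r"\n".join(
                        f"{a}: n={v['n']} mean={v['mean']:.3g}"
                        for a, v in sorted(per_arm.items()))
                else:
                    body = r"\n".join(
                        f"{a}: n={v['n']} RMST={v['rmst']:.4g}"
                        for a, v in sorted(per_arm.items()))
                label = f"node {n.id}\\nn={n.size}\\nbest: {n.besttrt}\\n{body}"
            else:
                label = (f"node {n.id}\\n{_dot_escape(n.split.describe())}"
                         f"\\nG={n.g:.4g}")
            lines.append(f'  n{n.id} [label="{label}"];')
        for n in tree.nodes:
            if not n.terminal:
                lines.append(f'  n{n.id} -> n{n.lchild} [label="yes"];')
                lines.append(f'  n{n.id} -> n{n.rchild} [label="no"];')
        lines.append("}")
        text = "\n".join(lines) + "\n"
        with open(path, "w") as fh:
            fh.write(text)
    elif fmt == "json":
        doc = {
            "outcome_kind": dataset.outcome_kind,
            "method": tree.method,
            "nodes": [
                {
                    "id": n.id, "depth": n.depth, "n": n.size,
                    "terminal": n.terminal,
                    "split": None if n.split is None else {
                        "variable": n.split.variable,
                        "var_type": n.split.var_type,
                        "cutpoint": n.split.cutpoint,
                        "subset": list(n.split.subset) if n.split.subset else None,
                    },
                    "G": n.g, "besttrt": str(n.besttrt),
                    "lchild": n.lchild, "rchild": n.rchild,
                }
                for n in tree.nodes
            ],
            "leaf_summaries": {str(k): v for k, v in summaries.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown render format {fmt!r}")


# ---------------------------------------------------------------------------
# CLI


def _read_config(path) -> dict:
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise click.ClickException(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            cfg[key.strip().replace("-", "_")] = value.strip()
    return cfg


def _dataset_from_flags(data, model, response, treatment, status, types):
    types_list = [t.strip() for t in types.split(",")] if types else None
    if model:
        return read_clinical_table(data, spec=model, types=types_list)
    return read_clinical_table(data, types=types_list, response=response,
                               treatment=treatment, status=status)


def _fit_tree(dataset, method, ntree, mtry, nmin, nmin2, maxdepth, maxdepth2,
              seed):
    forest = ForestParams(ntree=ntree, mtry=mtry, maxdepth2=maxdepth2,
                          nmin2=nmin2)
    params = TreeParams(method=method, nmin=nmin, maxdepth=maxdepth,
                        forest=forest, seed=seed)
    if method == "spm":
        return build_spm_tree(dataset, params)
    return build_dipm_tree(dataset, params)


def _write_scores(tree: Tree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "covariate", "score"])
        for n in tree.nodes:
            for name, score in (n.var_scores or {}).items():
                w.writerow([n.id, name, _fmt(score)])


_fit_options = [
    click.option("--data", required=True, type=click.Path(exists=True)),
    click.option("--model", default=None,
                 help='model text, e.g. "Y ~ treatment | X1 + X2"'),
    click.option("--response", default=None),
    click.option("--treatment", default=None),
    click.option("--status", default=None),
    click.option("--types", default=None,
                 help="comma-separated ordered role list for all columns"),
    click.option("--method", type=click.Choice(["dipm", "spm"]), default="dipm"),
    click.option("--ntree", type=int, default=50),
    click.option("--mtry", type=int, default=None),
    click.option("--nmin", type=int, default=20),
    click.option("--nmin2", type=int, default=None),
    click.option("--maxdepth", type=int, default=4),
    click.option("--maxdepth2", type=int, default=6),
    click.option("--seed", type=int, default=0),
    click.option("--log-level", default="WARNING"),
]


def _add_options(options):
    def wrap(fn):
        for opt in reversed(options):
            fn = opt(fn)
        return fn
    return wrap


@click.group()
def cli() -> None:
    """Subgroup-identification trees for precision medicine."""


@cli.command()
@_add_options(_fit_options)
@click.option("--config", type=click.Path(exists=True), default=None,
              help="key=value file mirroring the flags; CLI wins on conflict")
@click.option("--prune", is_flag=True, default=False)
@click.option("--out-tree", type=click.Path(), default=None)
@click.option("--out-render", type=click.Path(), default=None)
@click.option("--render-format", type=click.Choice(["dot", "json"]), default="dot")
@click.option("--out-scores", type=click.Path(), default=None)
@click.pass_context
def fit(ctx, config, **kw):
    """Fit a tree and write the node table (and optional render/scores)."""
    if config:
        cfg = _read_config(config)
        for key, value in cfg.items():
            if key not in kw:
                raise click.ClickException(f"unknown config key: {key}")
            src = ctx.get_parameter_source(key)
            if src is not None and src.name != "COMMANDLINE":
                param = next(p for p in ctx.command.params if p.name == key)
                kw[key] = param.type.convert(value, param, ctx)
    logging.basicConfig(level=kw["log_level"].upper())
    dataset = _dataset_from_flags(kw["data"], kw["model"], kw["response"],
                                  kw["treatment"], kw["status"], kw["types"])
    tree = _fit_tree(dataset, kw["method"], kw["ntree"], kw["mtry"], kw["nmin"],
                     kw["nmin2"], kw["maxdepth"], kw["maxdepth2"], kw["seed"])
    if kw["out_scores"]:
        _write_scores(tree, kw["out_scores"])
    if kw["prune"]:
        tree = prune_same_treatment(tree)
    if kw["out_tree"]:
        write_tree_table(tree, kw["out_tree"])
    else:
        w = csv.writer(sys.stdout)
        w.writerow(_TABLE_COLUMNS)
        for n in tree.nodes:
            w.writerow([n.id, n.depth, n.size,
                        n.split.variable if n.split else "",
                        n.split.var_type if n.split else "",
                        "" if n.split is None else
                        ("{" + ",".join(n.split.subset) + "}"
                         if n.split.var_type == "nominal" else _fmt(n.split.cutpoint)),
                        n.lchild or "", n.rchild or "", _fmt(n.g),
                        str(n.besttrt), int(n.terminal)])
    if kw["out_render"]:
        export_tree_render(tree, dataset, kw["out_render"], kw["render_format"])


@cli.command("score-table")
@_add_options(_fit_options)
@click.option("--out", required=True, type=click.Path())
def score_table(out, **kw):
    """Fit a forest-guided tree and dump per-node variable scores as CSV."""
    logging.basicConfig(level=kw["log_level"].upper())
    dataset = _dataset_from_flags(kw["data"], kw["model"], kw["response"],
                                  kw["treatment"], kw["status"], kw["types"])
    tree = _fit_tree(dataset, "dipm", kw["ntree"], kw["mtry"], kw["nmin"],
                     kw["nmin2"], kw["maxdepth"], kw["maxdepth2"], kw["seed"])
    _write_scores(tree, out)


@cli.command()
@click.option("--tree", "tree_path", required=True, type=click.Path(exists=True))
@click.option("--data", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def predict(tree_path, data, out):
    """Route new rows through a saved tree and write recommendations."""
    tree = read_tree_table(tree_path)
    df = pd.read_csv(data)
    pred = predict_optimal_treatment(tree, df)
    pred.to_csv(out, index=False)


@cli.command()
@click.option("--scenario", type=click.Choice(list(synthetic_data.PRESET_NAMES)),
              default="sign-reversal")
@click.option("--n", type=int, default=None)
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
@click.option("--out-truth", type=click.Path(), default=None)
def simulate(scenario, n, seed, out, out_truth):
    """Generate a synthetic randomized trial with a planted subgroup."""
    scn = synthetic_data.preset(scenario, n=n, seed=seed)
    if scn.outcome_kind == "continuous":
        dataset, truth = synthetic_data.simulate_continuous_trial(scn)
    else:
        dataset, truth = synthetic_data.simulate_survival_trial(scn)
    dataset.to_frame().to_csv(out, index=False)
    if out_truth:
        doc = dict(truth)
        doc["inside"] = [int(v) for v in truth["inside"]]
        doc["true_optimal"] = [int(v) for v in truth["true_optimal"]]
        with open(out_truth, "w") as fh:
            json.dump(doc, fh, indent=1)


def cli_main(argv=None) -> int:
    """Entry point; returns a process exit code instead of raising."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as exc:
        exc.show(file=sys.stderr)
        return exc.exit_code or 1
    except click.Abort:
        return 1
    except SystemExit as exc:  # --help and friends
        return int(exc.code or 0)
    except Exception as exc:  # noqa: BLE001 - one-line diagnostic, nonzero exit
        print(f"error: {exc}", file=sys.stderr)
        return 1
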