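"""Clinical dataset container, variable roles, and candidate-split enumeration.

A dataset for subgroup-identification trees carries one response column Y
(continuous, or a right-censored survival time with a 0/1 status column),
one treatment column with two or more arms, and candidate split covariates
typed ``binary``, ``ordinal`` or ``nominal``.  Higher Y is always the
clinically better direction; for survival data this means the event of
interest is harmful, so longer times are better.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableRole",
    "ClinicalDataset",
    "Split",
    "parse_types",
    "validate_dataset",
    "enumerate_candidate_splits",
    "NOMINAL_SPLIT_CAP",
]

ROLE_RESPONSE = "response"
ROLE_STATUS = "status"
ROLE_TREATMENT = "treatment"
COVARIATE_ROLES = ("binary", "ordinal", "nominal")
ALL_ROLES = (ROLE_RESPONSE, ROLE_STATUS, ROLE_TREATMENT) + COVARIATE_ROLES

#: above this many observed categories in a node, nominal splits fall back to
#: outcome-ordered (k-1)-split enumeration instead of all subsets
NOMINAL_SPLIT_CAP = 10


@dataclass(frozen=True)
class VariableRole:
    """A column name together with its role in the analysis."""

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ALL_ROLES:
            raise ValueError(f"unknown variable role {self.role!r} for column {self.name!r}")


@dataclass
class Split:
    """A candidate binary partition of a node.

    ``binary``/``ordinal`` variables split on a cutpoint c with the left
    child receiving {x <= c}; ``nominal`` variables split on a category
    subset S (stored as sorted original labels) with the left child
    receiving {x in S}.  The evaluated criterion is cached on the split.
    """

    variable: str
    var_type: str
    cutpoint: Optional[float] = None
    subset: Optional[tuple] = None
    criterion: Optional[object] = field(default=None, compare=False)

    def left_mask(self, dataset: "ClinicalDataset", rows: np.ndarray) -> np.ndarray:
        """Boolean mask over ``rows``: True = left child."""
        x = dataset.covariates[self.variable][rows]
        if self.var_type == "nominal":
            labels = dataset.category_labels[self.variable]
            codes = [i for i, lab in enumerate(labels) if str(lab) in self.subset]
            return np.isin(x, codes)
        return x <= self.cutpoint

    def describe(self) -> str:
        if self.var_type == "nominal":
            return f"{self.variable} in {{{','.join(str(s) for s in self.subset)}}}"
        return f"{self.variable} <= {self.cutpoint:g}"


@dataclass
class ClinicalDataset:
    """Validated rectangular trial data with role-typed columns.

    Treatment arms are recoded to consecutive integers 0..K-1 by first
    appearance; nominal covariates to category codes by sorted label.  The
    original labels are retained for reporting.
    """

    y: np.ndarray
    delta: Optional[np.ndarray]
    treatment: np.ndarray
    arm_labels: list
    covariates: dict
    covariate_types: dict
    category_labels: dict
    outcome_kind: str
    response_name: str = "Y"
    treatment_name: str = "treatment"
    status_name: Optional[str] = None
    _validated: bool = field(default=True, repr=False)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_arms(self) -> int:
        return len(self.arm_labels)

    @property
    def covariate_names(self) -> list:
        return list(self.covariates)

    def all_rows(self) -> np.ndarray:
        return np.arange(self.n)

    def arm_label(self, code: int) -> object:
        return self.arm_labels[int(code)]

    def to_frame(self) -> pd.DataFrame:
        """Reconstruct a plain table with original labels (column order:
        response, status, treatment, covariates)."""
        data = {self.response_name: self.y}
        if self.delta is not None:
            data[self.status_name] = self.delta
        data[self.treatment_name] = [self.arm_labels[a] for a in self.treatment]
        for name, values in self.covariates.items():
            if self.covariate_types[name] == "nominal":
                labels = self.category_labels[name]
                data[name] = [labels[int(v)] for v in values]
            else:
                data[name] = values
        return pd.DataFrame(data)


def parse_types(
    labels: Optional[Sequence[str]],
    columns: Sequence[str],
    outcome_kind: str = "continuous",
    response: Optional[str] = None,
    treatment: Optional[str] = None,
    status: Optional[str] = None,
) -> dict:
    """Build the column -> role map.

    ``labels``, when given, is an ordered list of role strings matching
    ``columns`` one-to-one.  When absent, the response/treatment (and status,
    for survival outcomes) columns must be named explicitly and every
    remaining column defaults to ordinal.
    """
    if outcome_kind not in ("continuous", "survival"):
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    columns = list(columns)
    if labels is not None:
        labels = list(labels)
        if len(labels) != len(columns):
            raise ValueError(
                f"types list has {len(labels)} entries for {len(columns)} columns"
            )
        roles = {}
        for name, role in zip(columns, labels):
            if role not in ALL_ROLES:
                raise ValueError(f"unknown variable type {role!r} for column {name!r}")
            roles[name] = role
    else:
        for flag, value in (("response", response), ("treatment", treatment)):
            if value is None:
                raise ValueError(f"no types given: the {flag} column must be named")
            if value not in columns:
                raise ValueError(f"{flag} column {value!r} not in table")
        if status is not None and status not in columns:
            raise ValueError(f"status column {status!r} not in table")
        roles = {}
        for name in columns:
            if name == response:
                roles[name] = ROLE_RESPONSE
            elif name == treatment:
                roles[name] = ROLE_TREATMENT
            elif status is not None and name == status:
                roles[name] = ROLE_STATUS
            else:
                roles[name] = "ordinal"
    _check_roles(roles, outcome_kind)
    return roles


def _check_roles(roles: dict, outcome_kind: str) -> None:
    counts = {r: 0 for r in ALL_ROLES}
    for role in roles.values():
        counts[role] += 1
    if counts[ROLE_RESPONSE] != 1:
        raise ValueError(
            f"exactly one response column required, found {counts[ROLE_RESPONSE]}"
        )
    if counts[ROLE_TREATMENT] != 1:
        raise ValueError(
            f"exactly one treatment column required, found {counts[ROLE_TREATMENT]}"
        )
    if counts[ROLE_STATUS] > 1:
        raise ValueError("at most one status column allowed")
    if outcome_kind == "continuous" and counts[ROLE_STATUS]:
        raise ValueError("status column given for a continuous outcome")
    if outcome_kind == "survival" and not counts[ROLE_STATUS]:
        raise ValueError("survival outcome requires a status column")


def _role_of(roles: dict, role: str) -> Optional[str]:
    for name, r in roles.items():
        if r == role:
            return name
    return None


def validate_dataset(raw, roles: Optional[dict] = None) -> ClinicalDataset:
    """Coerce and validate a raw table into a :class:`ClinicalDataset`.

    Complete cases only: any missing value in a role column is an error.
    Validation is idempotent — passing an already-validated dataset returns
    it unchanged.
    """
    if isinstance(raw, ClinicalDataset):
        return raw
    if roles is None:
        raise ValueError("roles are required when validating a raw table")
    df = pd.DataFrame(raw)
    for name in roles:
        if name not in df.columns:
            raise ValueError(f"role column {name!r} missing from table")

    response = _role_of(roles, ROLE_RESPONSE)
    status = _role_of(roles, ROLE_STATUS)
    treatment = _role_of(roles, ROLE_TREATMENT)
    outcome_kind = "survival" if status is not None else "continuous"
    _check_roles(roles, outcome_kind)

    for name in roles:
        col = df[name]
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {name!r} at row {row}")

    y = pd.to_numeric(df[response], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"non-numeric response value in column {response!r}")

    delta = None
    if status is not None:
        delta = pd.to_numeric(df[status], errors="coerce").to_numpy()
        if np.isnan(delta).any() or not np.isin(delta, (0, 1)).all():
            raise ValueError(f"status column {status!r} must be 0/1")
        delta = delta.astype(np.int64)
        if (y <= 0).any():
            raise ValueError("survival times must be strictly positive")

    # arms recoded by first appearance; the label map is kept for reporting
    trt_raw = df[treatment].to_numpy()
    arm_labels = list(pd.unique(trt_raw))
    if len(arm_labels) < 2:
        raise ValueError(f"treatment column has {len(arm_labels)} arm(s); need >= 2")
    code_of = {lab: i for i, lab in enumerate(arm_labels)}
    trt = np.array([code_of[v] for v in trt_raw], dtype=np.int64)

    covariates, cov_types, cat_labels = {}, {}, {}
    for name, role in roles.items():
        if role not in COVARIATE_ROLES:
            continue
        col = df[name]
        if role == "ordinal":
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"non-numeric ordinal covariate {name!r}")
        elif role == "binary":
            vals = pd.unique(col)
            if len(vals) > 2:
                raise ValueError(
                    f"binary covariate {name!r} has {len(vals)} distinct values"
                )
            if set(np.asarray(vals).tolist()) <= {0, 1, 0.0, 1.0}:
                x = col.to_numpy(dtype=float)
            else:
                order = sorted(vals, key=str)
                lut = {v: float(i) for i, v in enumerate(order)}
                x = np.array([lut[v] for v in col], dtype=float)
        else:  # nominal: codes by sorted label, keeps coding row-order invariant
            labels = sorted(pd.unique(col), key=str)
            lut = {v: i for i, v in enumerate(labels)}
            x = np.array([lut[v] for v in col], dtype=np.int64)
            cat_labels[name] = labels
        covariates[name] = x
        cov_types[name] = role

    return ClinicalDataset(
        y=y,
        delta=delta,
        treatment=trt,
        arm_labels=arm_labels,
        covariates=covariates,
        covariate_types=cov_types,
        category_labels=cat_labels,
        outcome_kind=outcome_kind,
        response_name=response,
        treatment_name=treatment,
        status_name=status,
    )


def _ordered_categories(dataset: ClinicalDataset, rows: np.ndarray, name: str) -> list:
    """Observed category codes ordered by within-node mean outcome
    (continuous) or event rate (survival); used above the subset cap."""
    x = dataset.covariates[name][rows]
    score = dataset.y[rows] if dataset.delta is None else dataset.delta[rows].astype(float)
    codes = np.unique(x)
    means = [score[x == c].mean() for c in codes]
    order = np.argsort(means, kind="stable")
    return [int(codes[i]) for i in order]


def enumerate_candidate_splits(
    dataset: ClinicalDataset, rows: np.ndarray, name: str
) -> list:
    """All candidate splits of covariate ``name`` within a node.

    Ordinal/binary: one split per midpoint between consecutive distinct
    observed values.  Nominal: one split per nonempty proper subset of the
    observed categories up to complement symmetry (the reported subset is
    the smaller side, ties broken lexicographically); above
    :data:`NOMINAL_SPLIT_CAP` observed categories only the k-1
    outcome-ordered splits are considered.  A variable constant in the node
    yields no splits.
    """
    var_type = dataset.covariate_types[name]
    x = dataset.covariates[name][rows]
    if var_type != "nominal":
        vals = np.unique(x)
        cuts = (vals[:-1] + vals[1:]) / 2.0
        return [Split(name, var_type, cutpoint=float(c)) for c in cuts]

    labels = dataset.category_labels[name]
    codes = np.unique(x)
    k = len(codes)
    if k < 2:
        return []
    if k > NOMINAL_SPLIT_CAP:
        ordered = _ordered_categories(dataset, rows, name)
        subsets = [tuple(sorted(str(labels[c]) for c in ordered[: i + 1]))
                   for i in range(k - 1)]
        return [Split(name, "nominal", subset=s) for s in subsets]

    observed = set(int(c) for c in codes)
    splits = []
    first = int(codes[0])
    rest = [int(c) for c in codes[1:]]
    for r in range(0, k - 1):
        for combo in itertools.combinations(rest, r):
            side = {first, *combo}
            other = observed - side
            # canonical subset: smaller side, then lexicographically first
            lab_a = tuple(sorted(str(labels[c]) for c in side))
            lab_b = tuple(sorted(str(labels[c]) for c in other))
            subset = min((len(lab_a), lab_a), (len(lab_b), lab_b))[1]
            splits.append(Split(name, "nominal", subset=subset))
    splits.sort(key=lambda s: (len(s.subset), s.subset))
    return splits
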