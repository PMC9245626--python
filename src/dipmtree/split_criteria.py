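"""Split-strength statistics G_t and node-level treatment summaries.

The strength of a candidate split is the treatment-by-split interaction
test statistic of the model appropriate to the outcome:

* continuous Y, 2 arms — squared Wald t of the interaction coefficient in
  ``E[Y] = b0 + b1*arm + b2*z + b3*arm*z`` (z = left-child indicator), df 1;
* continuous Y, K >= 3 arms — joint Wald chi-square of the K-1 interaction
  coefficients of the saturated arm-by-child two-way layout, df K-1;
* survival, 2 arms — squared Wald z of the interaction coefficient in the
  Cox proportional-hazards model with covariates (arm, z, arm*z), df 1;
* survival, K >= 3 arms — joint Wald chi-square of the K-1 hazard
  interaction coefficients, df K-1.

The continuous statistics are computed in closed form from arm-by-child
cell statistics (the models are saturated, so the OLS coefficient
estimates are cell-mean contrasts and their covariance is diagonal in the
cell means); the survival statistics use a Newton-Raphson partial
likelihood maximizer with Breslow tie handling.  A degenerate fit never
raises inside the tree search: it yields g = 0 with ``converged=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import ClinicalDataset, Split, enumerate_candidate_splits

__all__ = [
    "CriterionValue",
    "HazardsFit",
    "g_continuous_two_arm",
    "g_continuous_multi_arm",
    "fit_hazards",
    "g_survival_two_arm",
    "g_survival_multi_arm",
    "criterion_for",
    "optimal_treatment",
    "node_arm_summary",
    "km_estimate",
    "restricted_mean_survival_time",
    "best_split_for_variable",
]

logger = logging.getLogger(__name__)

#: minimum rows per arm-by-child cell for a continuous interaction fit
MIN_CELL = 2
#: residual sum of squares below this fraction of the total sum of squares
#: is treated as zero residual variance (degenerate fit)
_VAR_REL_TOL = 1e-10

_NEWTON_MAX_ITER = 25
_SCORE_TOL = 1e-8


@dataclass
class CriterionValue:
    """A split criterion G_t with its test degrees of freedom."""

    g: float
    df: int
    converged: bool


def _zero() -> CriterionValue:
    return CriterionValue(0.0, 0, False)


@dataclass
class HazardsFit:
    """Result of a Cox partial-likelihood maximization."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    degenerate: bool


# ---------------------------------------------------------------------------
# continuous outcomes: closed-form cell-statistic Wald tests


def _cont_cells(y, arm, z, n_arms):
    """Counts, sums and sums of squares per (arm, child) cell.

    Returns arrays of shape (K, 2); column 1 is the left child (z true).
    """
    idx = arm * 2 + z.astype(np.int64)
    m = 2 * n_arms
    n = np.bincount(idx, minlength=m).astype(float)
    s = np.bincount(idx, weights=y, minlength=m)
    q = np.bincount(idx, weights=y * y, minlength=m)
    return n.reshape(-1, 2), s.reshape(-1, 2), q.reshape(-1, 2)


def _g_cont_from_cells(n, s, q) -> CriterionValue:
    """Interaction Wald statistic from (K, 2) cell statistics."""
    K = n.shape[0]
    ntot = n.sum()
    df_resid = ntot - 2 * K
    if (n < MIN_CELL).any() or df_resid < 1:
        return _zero()
    m = s / n
    sse = float((q - s * s / n).sum())
    if sse <= _VAR_REL_TOL * max(float(q.sum()), 1.0):
        return _zero()
    s2 = sse / df_resid
    if K == 2:
        b3 = m[1, 1] - m[1, 0] - m[0, 1] + m[0, 0]
        var = s2 * (1.0 / n).sum()
        return CriterionValue(float(b3 * b3 / var), 1, True)
    # joint Wald for K-1 interaction contrasts; their covariance is
    # s2 * (a * 11' + diag(d)), inverted by Sherman-Morrison
    delta = (m[1:, 1] - m[1:, 0]) - (m[0, 1] - m[0, 0])
    d = 1.0 / n[1:, 1] + 1.0 / n[1:, 0]
    a = 1.0 / n[0, 1] + 1.0 / n[0, 0]
    inv_d = 1.0 / d
    g = (np.sum(delta * delta * inv_d)
         - a * np.sum(delta * inv_d) ** 2 / (1.0 + a * inv_d.sum())) / s2
    return CriterionValue(max(float(g), 0.0), K - 1, True)


def g_continuous_two_arm(y, arm, z) -> CriterionValue:
    """Squared interaction Wald t for a continuous outcome, two arms."""
    y = np.asarray(y, dtype=float)
    arm = np.asarray(arm, dtype=np.int64)
    z = np.asarray(z, dtype=bool)
    n, s, q = _cont_cells(y, arm, z, 2)
    return _g_cont_from_cells(n, s, q)


def g_continuous_multi_arm(y, arm, z) -> CriterionValue:
    """Joint interaction Wald chi-square for a continuous outcome, K >= 3 arms."""
    y = np.asarray(y, dtype=float)
    arm = np.asarray(arm, dtype=np.int64)
    z = np.asarray(z, dtype=bool)
    K = int(arm.max()) + 1
    if K < 3:
        raise ValueError("g_continuous_multi_arm requires at least 3 arms")
    if len(np.unique(arm)) != K:
        raise ValueError("every arm must be present in the node")
    n, s, q = _cont_cells(y, arm, z, K)
    return _g_cont_from_cells(n, s, q)


# ---------------------------------------------------------------------------
# survival outcomes: Cox partial likelihood (Breslow ties)


def _partial_lik(beta, t, d, X, first):
    """Breslow log partial likelihood with score vector and information."""
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wX[::-1], axis=0)[::-1]
    s2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    ev = d == 1
    fi = first[ev]
    xbar = s1[fi] / s0[fi, None]
    ll = float((eta[ev] - shift).sum() - np.log(s0[fi]).sum())
    score = X[ev].sum(axis=0) - xbar.sum(axis=0)
    info = (s2[fi] / s0[fi, None, None]).sum(axis=0) - xbar.T @ xbar
    return ll, score, info


def fit_hazards(times, delta, X, max_iter: int = _NEWTON_MAX_ITER,
                score_tol: float = _SCORE_TOL) -> HazardsFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Ties are handled with the Breslow approximation.  The step is halved
    when the log likelihood decreases.  Deterministic given inputs; raises
    only when there are no events.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=np.int64)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if int(delta.sum()) == 0:
        raise ValueError("no events: cannot fit a proportional-hazards model")

    order = np.argsort(times, kind="stable")
    t, d, Xs = times[order], delta[order], X[order]
    n, p = Xs.shape
    # index of the first subject sharing each subject's time (risk-set entry)
    starts = np.concatenate(([0], np.flatnonzero(t[1:] != t[:-1]) + 1))
    lengths = np.diff(np.append(starts, n))
    first = np.repeat(starts, lengths)

    beta = np.zeros(p)
    ll, score, info = _partial_lik(beta, t, d, Xs, first)
    converged = bool(np.max(np.abs(score)) < score_tol)
    it = 0
    while not converged and it < max_iter:
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            break
        # step-halving keeps the likelihood non-decreasing
        new_ll, new_score, new_info = _partial_lik(beta + step, t, d, Xs, first)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-10) and halvings < 20:
            step *= 0.5
            new_ll, new_score, new_info = _partial_lik(beta + step, t, d, Xs, first)
            halvings += 1
        if not np.isfinite(new_ll):
            break
        beta = beta + step
        ll, score, info = new_ll, new_score, new_info
        it += 1
        converged = bool(np.max(np.abs(score)) < score_tol)

    rank = np.linalg.matrix_rank(info) if np.all(np.isfinite(info)) else 0
    degenerate = rank < p
    cov = np.linalg.pinv(info) if np.all(np.isfinite(info)) else np.full((p, p), np.nan)
    return HazardsFit(coef=beta, cov=cov, loglik=ll, n_iter=it,
                      converged=converged, degenerate=degenerate)


def _surv_admissible(delta, arm, z, n_arms) -> bool:
    if int(delta[z].sum()) < 1 or int(delta[~z].sum()) < 1:
        return False
    idx = arm * 2 + z.astype(np.int64)
    cells = np.bincount(idx, minlength=2 * n_arms)
    return bool((cells > 0).all())


def g_survival_two_arm(times, delta, arm, z) -> CriterionValue:
    """Squared interaction Wald z in the Cox model (arm, z, arm*z)."""
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=np.int64)
    arm = np.asarray(arm, dtype=np.int64)
    z = np.asarray(z, dtype=bool)
    if not _surv_admissible(delta, arm, z, 2):
        return _zero()
    X = np.column_stack([arm, z, arm * z]).astype(float)
    try:
        fit = fit_hazards(times, delta, X)
    except (ValueError, np.linalg.LinAlgError):
        return _zero()
    var = fit.cov[2, 2]
    if not fit.converged or fit.degenerate or not np.isfinite(var) or var <= 0:
        return _zero()
    return CriterionValue(float(fit.coef[2] ** 2 / var), 1, True)


def g_survival_multi_arm(times, delta, arm, z) -> CriterionValue:
    """Joint interaction Wald chi-square in the Cox model, K >= 3 arms."""
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=np.int64)
    arm = np.asarray(arm, dtype=np.int64)
    z = np.asarray(z, dtype=bool)
    K = int(arm.max()) + 1
    if K < 3:
        raise ValueError("g_survival_multi_arm requires at least 3 arms")
    if len(np.unique(arm)) != K:
        raise ValueError("every arm must be present in the node")
    if int(delta.sum()) < K or not _surv_admissible(delta, arm, z, K):
        return _zero()
    dummies = [(arm == k).astype(float) for k in range(1, K)]
    zf = z.astype(float)
    X = np.column_stack(dummies + [zf] + [dk * zf for dk in dummies])
    try:
        fit = fit_hazards(times, delta, X)
    except (ValueError, np.linalg.LinAlgError):
        return _zero()
    if not fit.converged or fit.degenerate:
        return _zero()
    idx = np.arange(K, 2 * K - 1)  # interaction block
    b = fit.coef[idx]
    C = fit.cov[np.ix_(idx, idx)]
    try:
        g = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError:
        return _zero()
    if not np.isfinite(g) or g < 0:
        return _zero()
    return CriterionValue(g, K - 1, True)


# ---------------------------------------------------------------------------
# dispatch


def _node_arrays(dataset: ClinicalDataset, rows: np.ndarray):
    y = dataset.y[rows]
    delta = dataset.delta[rows] if dataset.delta is not None else None
    arm = dataset.treatment[rows]
    return y, delta, arm


def _g_dispatch(y, delta, arm_recoded, z, survival: bool) -> CriterionValue:
    K = int(arm_recoded.max()) + 1
    if survival:
        if K == 2:
            return g_survival_two_arm(y, delta, arm_recoded, z)
        return g_survival_multi_arm(y, delta, arm_recoded, z)
    if K == 2:
        return g_continuous_two_arm(y, arm_recoded, z)
    return g_continuous_multi_arm(y, arm_recoded, z)


def criterion_for(dataset: ClinicalDataset, rows: np.ndarray, split: Split) -> CriterionValue:
    """Evaluate G_t for one candidate split of a node.

    Dispatches on the outcome kind and on the number of treatment arms
    present in the node; the value is cached on the split.
    """
    z = split.left_mask(dataset, rows)
    if not z.any() or z.all():
        split.criterion = _zero()
        return split.criterion
    y, delta, arm = _node_arrays(dataset, rows)
    present = np.unique(arm)
    if len(present) < 2:
        split.criterion = _zero()
        return split.criterion
    arm_r = np.searchsorted(present, arm)
    split.criterion = _g_dispatch(y, delta, arm_r, z, dataset.outcome_kind == "survival")
    return split.criterion


# ---------------------------------------------------------------------------
# node treatment summaries: mean response / restricted mean survival time


def km_estimate(times, delta):
    """Kaplan-Meier product-limit estimate as step-function points.

    Returns ``(t, s)`` arrays beginning at (0, 1.0) with one point per
    distinct event time.  At tied times deaths precede censorings: subjects
    censored at t remain in the risk set for deaths at t.
    """
    times = np.asarray(times, dtype=float)
    delta = np.asarray(delta, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    t, d = times[order], delta[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    at_risk = n - start
    deaths = np.add.reduceat(d, start)
    keep = deaths > 0
    surv = np.cumprod(1.0 - deaths[keep] / at_risk[keep])
    return (np.concatenate(([0.0], uniq[keep])),
            np.concatenate(([1.0], surv)))


def restricted_mean_survival_time(times, delta, tau: float) -> float:
    """Area under the Kaplan-Meier curve on [0, tau]."""
    t, s = km_estimate(times, delta)
    tau = float(tau)
    t = np.append(t, np.inf)
    total = 0.0
    for k in range(len(s)):
        lo, hi = t[k], min(t[k + 1], tau)
        if hi <= lo:
            break
        total += s[k] * (hi - lo)
    return total


def node_arm_summary(dataset: ClinicalDataset, rows: np.ndarray) -> dict:
    """Per-arm outcome summary of a node: mean Y (continuous) or RMST
    truncated at the node's largest observed time (survival).

    Keys are arm codes; arms absent from the node are omitted.
    """
    y, delta, arm = _node_arrays(dataset, rows)
    out = {}
    if dataset.outcome_kind == "continuous":
        for a in np.unique(arm):
            out[int(a)] = float(y[arm == a].mean())
    else:
        tau = float(y.max())
        for a in np.unique(arm):
            sel = arm == a
            out[int(a)] = restricted_mean_survival_time(y[sel], delta[sel], tau)
    return out


def optimal_treatment(dataset: ClinicalDataset, rows: np.ndarray) -> int:
    """Arm code with the best within-node outcome summary.

    Continuous outcomes use the within-arm mean of Y (higher is better);
    survival outcomes the restricted mean survival time.  Ties go to the
    smallest arm code.
    """
    summary = node_arm_summary(dataset, rows)
    best, best_val = None, -np.inf
    for code in sorted(summary):
        if summary[code] > best_val:
            best, best_val = code, summary[code]
    return int(best)


def outcome_degenerate(dataset: ClinicalDataset, rows: np.ndarray) -> bool:
    """True when the node outcome carries no usable signal: a constant
    continuous response, or a survival node with no events or a single
    observed time."""
    y = dataset.y[rows]
    if dataset.outcome_kind == "continuous":
        return bool(y.max() == y.min())
    return int(dataset.delta[rows].sum()) == 0 or bool(y.max() == y.min())


# ---------------------------------------------------------------------------
# best split of one variable within a node


def _best_ordinal_continuous(y, arm_r, x, K, min_child):
    """Vectorized scan over all midpoint cutpoints of an ordinal variable."""
    order = np.argsort(x, kind="stable")
    xs, ys, as_ = x[order], y[order], arm_r[order]
    b = np.flatnonzero(xs[1:] != xs[:-1])
    if len(b) == 0:
        return None, None
    cuts = (xs[b] + xs[b + 1]) / 2.0
    ntot = len(xs)
    K2 = 2 * K
    nL = np.empty((K, len(b)))
    sL = np.empty((K, len(b)))
    qL = np.empty((K, len(b)))
    nT = np.empty(K)
    sT = np.empty(K)
    qT = np.empty(K)
    for a in range(K):
        ind = (as_ == a).astype(float)
        nL[a] = np.cumsum(ind)[b]
        sL[a] = np.cumsum(ind * ys)[b]
        qL[a] = np.cumsum(ind * ys * ys)[b]
        nT[a], sT[a], qT[a] = ind.sum(), (ind * ys).sum(), (ind * ys * ys).sum()
    nR = nT[:, None] - nL
    sR = sT[:, None] - sL
    qR = qT[:, None] - qL

    ok = (nL >= MIN_CELL).all(axis=0) & (nR >= MIN_CELL).all(axis=0)
    ok &= (nL.sum(axis=0) >= min_child) & (nR.sum(axis=0) >= min_child)
    df_resid = ntot - K2
    if df_resid < 1 or not ok.any():
        return None, None
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = (np.where(nL > 0, qL - sL * sL / nL, 0.0).sum(axis=0)
               + np.where(nR > 0, qR - sR * sR / nR, 0.0).sum(axis=0))
        ok &= sse > _VAR_REL_TOL * max(float(qT.sum()), 1.0)
        s2 = sse / df_resid
        mL = sL / nL
        mR = sR / nR
        if K == 2:
            b3 = (mL[1] - mR[1]) - (mL[0] - mR[0])
            var = s2 * (1.0 / nL + 1.0 / nR).sum(axis=0)
            g = b3 * b3 / var
        else:
            delta = (mL[1:] - mR[1:]) - (mL[0] - mR[0])
            d = 1.0 / nL[1:] + 1.0 / nR[1:]
            a0 = 1.0 / nL[0] + 1.0 / nR[0]
            inv_d = 1.0 / d
            g = ((delta * delta * inv_d).sum(axis=0)
                 - a0 * (delta * inv_d).sum(axis=0) ** 2
                 / (1.0 + a0 * inv_d.sum(axis=0))) / s2
    g = np.where(ok & np.isfinite(g), g, -np.inf)
    i = int(np.argmax(g))  # ascending cuts: ties go to the smaller cutpoint
    if not np.isfinite(g[i]):
        return None, None
    return float(cuts[i]), float(g[i])


def best_split_for_variable(
    dataset: ClinicalDataset,
    rows: np.ndarray,
    name: str,
    min_child: int = 1,
) -> Optional[Split]:
    """Best admissible split of covariate ``name`` within a node.

    Scans every candidate split (midpoints for binary/ordinal, category
    subsets for nominal), maximizing G_t; ties prefer the smaller cutpoint
    or the lexicographically first subset.  Returns ``None`` when no
    candidate is admissible.  The returned split carries its criterion
    (re-evaluated through :func:`criterion_for` on the node rows).
    """
    y, delta, arm = _node_arrays(dataset, rows)
    present = np.unique(arm)
    if len(present) < 2:
        return None
    arm_r = np.searchsorted(present, arm)
    K = len(present)
    survival = dataset.outcome_kind == "survival"
    var_type = dataset.covariate_types[name]
    x = dataset.covariates[name][rows]

    best = None
    if var_type != "nominal" and not survival:
        cut, _ = _best_ordinal_continuous(y, arm_r, x.astype(float), K, min_child)
        if cut is not None:
            best = Split(name, var_type, cutpoint=cut)
    else:
        best_g = 0.0
        found = False
        for cand in enumerate_candidate_splits(dataset, rows, name):
            z = cand.left_mask(dataset, rows)
            nl = int(z.sum())
            if nl < min_child or len(z) - nl < min_child:
                continue
            cv = _g_dispatch(y, delta, arm_r, z, survival)
            if cv.converged and (not found or cv.g > best_g):
                best, best_g, found = cand, cv.g, True
        if not found:
            return None

    if best is None:
        return None
    cv = criterion_for(dataset, rows, best)
    if not cv.converged:
        return None
    return best
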