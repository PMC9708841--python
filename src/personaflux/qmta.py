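"""Quadratic metabolic transformation: personalised flux maps.

Given an organ reference flux distribution v_ref and one individual's
reaction activity fold changes FC, the personalised flux map is the solution
of the strictly convex quadratic programme

    minimise  w * sum_{i in Ru} (v_ref_i - v_i)^2 / max(|v_ref_i|, m)
            +     sum_{i in Re} (v_ref_i * FC_i - v_i)^2
                                / max((v_ref_i * (FC_i - 1))^2, m)
    subject to  S v = 0,  lb <= v <= ub

where Re are reactions mapped to imputed expression (target
``v_ref_i * FC_i``), Ru the unmapped remainder (target ``v_ref_i``), ``w``
weighs deviation of unmapped reactions and ``m`` floors the per-reaction
scaling so reactions with near-zero reference flux or fold change 1 do not
blow up the objective.  Both terms are scaled by the reference distribution
to avoid biasing the fit towards high-flux reactions.

Solved on the reversible-split network, so all fluxes are non-negative and a
formerly reversible reaction's two directions each carry their own target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, minimize

from .exceptions import SolverError, ValidationError
from .network import MetabolicNetwork, flux_violation

DEFAULT_W = 1.0
DEFAULT_M = 1e-6
#: pseudo-flux added inside log2 so zero fluxes transform finitely
DEFAULT_LOG_EPSILON = 1e-9

#: hyperparameter grids explored when tuning (w, m) against feature data
DEFAULT_W_GRID = (100.0, 10.0, 1.0, 0.1, 0.01)
DEFAULT_M_GRID = (1e-6, 1e-7, 1e-8, 1e-9, 1e-10, 1e-11, 1e-12)


@dataclass
class QmtaProblem:
    """Assembled per-individual QP: targets t and positive coefficients c so
    the objective is ``sum_i c_i (v_i - t_i)^2``."""

    network: MetabolicNetwork
    targets: np.ndarray
    coefficients: np.ndarray
    mapped: list[str]
    unmapped: list[str]
    w: float
    m: float

    def objective_at(self, v: pd.Series | np.ndarray) -> float:
        x = (
            v.reindex(self.network.reaction_ids).to_numpy(dtype=float)
            if isinstance(v, pd.Series)
            else np.asarray(v, dtype=float)
        )
        return float(self.coefficients @ (x - self.targets) ** 2)


def build_problem(
    net: MetabolicNetwork,
    v_ref: pd.Series,
    fc_column: pd.Series,
    w: float = DEFAULT_W,
    m: float = DEFAULT_M,
) -> QmtaProblem:
    """Assemble the QP for one individual.

    ``fc_column`` carries fold changes for the expression-mapped reactions
    (all positive); every other network reaction is treated as unmapped and
    anchored at its reference flux.
    """
    if w <= 0 or m <= 0:
        raise ValidationError(f"w and m must be > 0 (got w={w}, m={m})")
    rids = net.reaction_ids
    missing = set(rids) - set(v_ref.index)
    if missing:
        raise ValidationError(f"v_ref does not cover reactions {sorted(missing)[:5]}")
    fc = fc_column.dropna()
    if (fc <= 0).any():
        raise ValidationError("fold changes must be positive")
    mapped = [rid for rid in rids if rid in fc.index]
    unmapped = [rid for rid in rids if rid not in fc.index]
    vref = v_ref.reindex(rids).to_numpy(dtype=float)
    t = vref.copy()
    c = np.empty(len(rids))
    idx = {rid: j for j, rid in enumerate(rids)}
    for rid in unmapped:
        j = idx[rid]
        c[j] = w / max(abs(vref[j]), m)
    for rid in mapped:
        j = idx[rid]
        f = float(fc.loc[rid])
        t[j] = vref[j] * f
        c[j] = 1.0 / max((vref[j] * (f - 1.0)) ** 2, m)
    return QmtaProblem(net, t, c, mapped, unmapped, w, m)


def solve_qmta(
    problem: QmtaProblem,
    x0: np.ndarray | None = None,
    tol: float = 1e-12,
    feasibility_tol: float = 1e-6,
) -> tuple[pd.Series, float, str]:
    """Solve the personalisation QP.

    Strict convexity (all coefficients positive) makes the minimiser unique.
    A reduced sequential quadratic programming solve from the reference point
    is attempted first, with an interior-point fallback; the returned vector
    is checked against mass balance and bounds.

    Returns (flux vector, objective value, solver status).
    """
    net = problem.network
    S, _ = net.stoichiometric_matrix()
    lb, ub = net.bounds_arrays()
    A, b = net.inequality_arrays()
    t, c = problem.targets, problem.coefficients

    def fun(x):
        d = x - t
        return float(c @ d**2)

    def jac(x):
        return 2.0 * c * (x - t)

    if x0 is None:
        x0 = np.clip(t, lb, ub)
    cons = []
    if S.shape[0]:
        cons.append({"type": "eq", "fun": lambda x: S @ x, "jac": lambda x: S})
    if A.shape[0]:
        cons.append({"type": "ineq", "fun": lambda x: b - A @ x, "jac": lambda x: -A})
    res = minimize(
        fun,
        x0,
        jac=jac,
        bounds=np.column_stack([lb, ub]),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": tol},
    )
    x, status = res.x, "optimal" if res.success else f"slsqp:{res.message}"
    viol = flux_violation(net, pd.Series(x, index=net.reaction_ids))
    if not res.success or viol > feasibility_tol:
        tc = []
        if S.shape[0]:
            tc.append(LinearConstraint(S, 0.0, 0.0))
        if A.shape[0]:
            tc.append(LinearConstraint(A, -np.inf, b))
        res2 = minimize(
            fun,
            np.clip(x0, lb, ub),
            jac=jac,
            hess=lambda x: np.diag(2.0 * c),
            bounds=np.column_stack([lb, ub]),
            constraints=tc,
            method="trust-constr",
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
        )
        x2 = np.clip(res2.x, lb, ub)
        viol2 = flux_violation(net, pd.Series(x2, index=net.reaction_ids))
        if viol2 <= feasibility_tol and (viol > feasibility_tol or res2.fun < res.fun):
            x, status = x2, "optimal" if res2.status in (1, 2) else f"trust-constr:{res2.status}"
            viol = viol2
    if viol > feasibility_tol:
        raise SolverError(
            f"qMTA solution violates constraints by {viol:.2e} (> {feasibility_tol:.0e})"
        )
    fluxes = pd.Series(x, index=net.reaction_ids)
    return fluxes, problem.objective_at(fluxes), status


def batch_personalize(
    net: MetabolicNetwork,
    v_ref: pd.Series,
    fold_changes: pd.DataFrame,
    w: float = DEFAULT_W,
    m: float = DEFAULT_M,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Solve the QP independently for every individual (column) in
    ``fold_changes``.

    Returns (raw flux matrix individual x reaction, objective values,
    solver statuses); failed individuals get NaN rows and a failure status
    rather than aborting the cohort.
    """
    rows, objs, statuses = {}, {}, {}
    failures = []
    for ind in fold_changes.columns:
        problem = build_problem(net, v_ref, fold_changes[ind], w=w, m=m)
        try:
            flux, obj, status = solve_qmta(problem)
        except SolverError as exc:
            failures.append(ind)
            rows[ind] = pd.Series(np.nan, index=net.reaction_ids)
            objs[ind], statuses[ind] = np.nan, f"failed: {exc}"
            continue
        rows[ind], objs[ind], statuses[ind] = flux, obj, status
    if failures:
        warnings.warn(f"qMTA failed for {len(failures)} individuals: {failures[:5]}")
    raw = pd.DataFrame(rows).T
    raw.index.name = "individual"
    return raw, pd.Series(objs), pd.Series(statuses)


def transform_fluxes(
    raw: pd.DataFrame, epsilon: float = DEFAULT_LOG_EPSILON
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """log2 and z-score layers of a raw flux matrix (individual x reaction).

    Fluxes must be non-negative (split network); the log2 layer is
    ``log2(v + epsilon)`` and the standardised layer z-scores each reaction
    with the sample (n-1) standard deviation.  Zero-variance reactions are
    set to 0 and flagged.
    """
    if (raw < -1e-9).any().any():
        raise ValidationError("raw fluxes must be non-negative; split the network first")
    log2 = np.log2(raw.clip(lower=0.0) + epsilon)
    mu = log2.mean(axis=0)
    sd = log2.std(axis=0, ddof=1) if len(log2) > 1 else pd.Series(0.0, index=log2.columns)
    zero_var = sd.fillna(0.0) <= 0
    std = (log2 - mu).div(sd.where(~zero_var, 1.0), axis=1)
    std.loc[:, zero_var] = 0.0
    return log2, std, zero_var


@dataclass
class QmtaResults:
    """Personalised flux maps for a cohort.

    ``raw`` holds the QP solutions (mol/day), ``log2`` and ``standardised``
    the transformed layers used downstream in association testing.
    """

    raw: pd.DataFrame
    log2: pd.DataFrame
    standardised: pd.DataFrame
    objective_values: pd.Series
    statuses: pd.Series
    zero_variance: pd.Series
    w: float
    m: float

    @property
    def n_individuals(self) -> int:
        return len(self.raw)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_flux": self.raw.mean(axis=0),
                "sd_flux": self.raw.std(axis=0, ddof=1),
                "zero_variance": self.zero_variance,
            }
        )


class QmtaModel:
    """Cohort-level personalisation model, statsmodels-style.

    Parameters
    ----------
    network
        Reversible-split organ network.
    v_ref
        Reference flux distribution covering every reaction.
    fold_changes
        Reaction x individual fold-change matrix (positive entries).
    w, m
        Unmapped-deviation weight and scaling floor.
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        v_ref: pd.Series,
        fold_changes: pd.DataFrame,
        w: float = DEFAULT_W,
        m: float = DEFAULT_M,
    ):
        if w <= 0 or m <= 0:
            raise ValidationError(f"w and m must be > 0 (got w={w}, m={m})")
        self.network = network
        self.v_ref = v_ref
        self.fold_changes = fold_changes
        self.w = w
        self.m = m

    def fit(self, epsilon: float = DEFAULT_LOG_EPSILON) -> QmtaResults:
        raw, objs, statuses = batch_personalize(
            self.network, self.v_ref, self.fold_changes, w=self.w, m=self.m
        )
        ok = raw.dropna()
        log2, std, zero_var = transform_fluxes(ok, epsilon=epsilon)
        log2 = log2.reindex(raw.index)
        std = std.reindex(raw.index)
        return QmtaResults(raw, log2, std, objs, statuses, zero_var, self.w, self.m)


def grid_search_hyperparams(
    net: MetabolicNetwork,
    v_ref: pd.Series,
    fold_changes: pd.DataFrame,
    features: pd.DataFrame,
    w_grid=DEFAULT_W_GRID,
    m_grid=DEFAULT_M_GRID,
    flux_prune_threshold: float = 0.9,
    min_overlap: int = 10,
) -> tuple[float, float, pd.DataFrame]:
    """Tune (w, m) by total variance explained against feature data.

    For every grid cell the cohort is personalised, fluxes transformed and
    pruned for collinearity, and the linear fluxome-wide association run
    against the (already preprocessed) features; the cell score is the sum of
    R-squared over all tested flux-feature pairs.  Returns the best (w, m)
    and the full score table; cells that fail to solve get a missing score.
    Ties break towards the earlier grid entry, making the search
    deterministic.
    """
    from .fwas import LinearFwas, prune_correlated

    if not len(w_grid) or not len(m_grid):
        raise ValidationError("hyperparameter grids must be non-empty")
    records = []
    best = (None, None, -np.inf)
    for w in w_grid:
        for m in m_grid:
            try:
                res = QmtaModel(net, v_ref, fold_changes, w=w, m=m).fit()
                kept = prune_correlated(res.standardised, flux_prune_threshold)
                fw = LinearFwas(
                    res.standardised[kept], features, min_overlap=min_overlap
                ).fit()
                score = float((fw.table["r_squared"]).sum())
            except Exception as exc:  # a failing cell is recorded, not fatal
                warnings.warn(f"grid cell (w={w}, m={m}) failed: {exc}")
                score = np.nan
            records.append({"w": w, "m": m, "sum_r_squared": score})
            if np.isfinite(score) and score > best[2]:
                best = (w, m, score)
    table = pd.DataFrame(records)
    if best[0] is None:
        raise SolverError("every hyperparameter grid cell failed")
    return best[0], best[1], table
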