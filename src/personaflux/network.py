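"""Constraint-based metabolic networks and the linear-programming layer.

A :class:`MetabolicNetwork` is a stoichiometric model: metabolites (rows),
reactions (columns), flux bounds, gene sets and subsystem labels.  Metabolites
flagged ``boundary`` are held at constant concentration and impose no
mass-balance row, which is how an organ subnetwork exchanging material with
blood or bile is made self-contained.

Feasibility is the polytope  {v : S v = 0, lb <= v <= ub, A v <= b}  where S
has one row per non-boundary metabolite and the optional inequality rows A
carry constraints added later in the pipeline (e.g. the near-optimality
restriction of an expression-weighted flux minimisation).

All linear programmes are solved with the HiGHS solver behind
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import InfeasibleError, ValidationError

#: default LP feasibility/optimality tolerance handed to HiGHS
LP_TOL = 1e-9
#: tolerance at which a flux vector is reported feasible
FEASIBILITY_TOL = 1e-6
#: default upper bound for synthetic source/sink reactions
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``boundary=True`` marks a species whose concentration is assumed constant
    (e.g. a blood metabolite seen from an organ model); it contributes no
    mass-balance constraint.
    """

    id: str
    compartment: str = ""
    boundary: bool = False


@dataclass
class Reaction:
    """A biochemical reaction or transport process.

    ``stoich`` maps metabolite ids to signed coefficients (negative =
    consumed).  ``genes`` is the flattened set of genes whose products
    catalyse the reaction; AND/OR structure of the original rule is not kept.
    Bounds are fluxes in mol/day.
    """

    id: str
    stoich: dict[str, float] = field(default_factory=dict)
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""
    genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.name:
            self.name = self.id
        self.genes = frozenset(self.genes)


@dataclass
class TaskSpec:
    """A metabolic task: produce the required outputs from the allowed inputs.

    ``required_outputs`` maps metabolite ids to minimum production rates
    (mol/day, strictly positive).
    """

    id: str
    allowed_inputs: frozenset[str] = frozenset()
    required_outputs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.allowed_inputs = frozenset(self.allowed_inputs)
        bad = {k: v for k, v in self.required_outputs.items() if v <= 0}
        if bad:
            raise ValidationError(f"task {self.id!r}: required rates must be > 0, got {bad}")


class MetabolicNetwork:
    """A stoichiometric network with bounds, genes and optional extra rows.

    Parameters
    ----------
    metabolites, reactions
        Network members; ids must be unique and every stoichiometry key must
        resolve to a declared metabolite.
    inequalities
        Extra linear rows, each ``(coefficients, upper)`` meaning
        ``sum(coefficients[rid] * v[rid]) <= upper``.
    """

    def __init__(self, metabolites, reactions, inequalities=None, id=""):
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.inequalities: list[tuple[dict[str, float], float]] = list(inequalities or [])
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        rids = [r.id for r in self.reactions]
        for kind, ids in (("metabolite", mids), ("reaction", rids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicate {kind} id {i!r}")
                seen.add(i)
        declared = set(mids)
        for r in self.reactions:
            if r.lb > r.ub:
                raise ValidationError(f"reaction {r.id!r}: lb {r.lb} > ub {r.ub}")
            missing = set(r.stoich) - declared
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {sorted(missing)}"
                )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            [replace(m) for m in self.metabolites],
            [replace(r, stoich=dict(r.stoich)) for r in self.reactions],
            [(dict(c), u) for c, u in self.inequalities],
            id=self.id,
        )

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense S with one row per non-boundary metabolite.

        Returns (S, row metabolite ids); columns follow ``reaction_ids``.
        """
        rows = [m.id for m in self.metabolites if not m.boundary]
        ridx = {m: i for i, m in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoich.items():
                i = ridx.get(mid)
                if i is not None:
                    S[i, j] += coef
        return S, rows

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([r.lb for r in self.reactions], dtype=float),
            np.array([r.ub for r in self.reactions], dtype=float),
        )

    def inequality_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Extra rows as (A, b) with A v <= b; A has 0 rows when none exist."""
        n = len(self.reactions)
        ridx = {rid: j for j, rid in enumerate(self.reaction_ids)}
        A = np.zeros((len(self.inequalities), n))
        b = np.zeros(len(self.inequalities))
        for i, (coeffs, upper) in enumerate(self.inequalities):
            for rid, c in coeffs.items():
                A[i, ridx[rid]] = c
            b[i] = upper
        return A, b

    def is_exchange(self, reaction: Reaction) -> bool:
        """Whether a reaction creates or destroys internal mass.

        True when its stoichiometry, restricted to non-boundary metabolites,
        is empty or single-signed — this covers plain exchanges (``A ->``)
        and transport across a constant-concentration boundary.
        """
        boundary = {m.id for m in self.metabolites if m.boundary}
        coeffs = [c for mid, c in reaction.stoich.items() if mid not in boundary and c != 0]
        if not coeffs:
            return True
        return all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs)

    @property
    def exchange_reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions if self.is_exchange(r)]

    def __repr__(self):
        return (
            f"<MetabolicNetwork {self.id!r}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.inequalities)} extra constraints>"
        )


# -- linear programming ----------------------------------------------------


@dataclass
class LPSolution:
    objective_value: float
    fluxes: pd.Series
    status: str


def _objective_vector(net: MetabolicNetwork, objective: dict[str, float]) -> np.ndarray:
    ridx = {rid: j for j, rid in enumerate(net.reaction_ids)}
    c = np.zeros(len(net.reactions))
    for rid, coef in objective.items():
        if rid not in ridx:
            raise KeyError(f"objective references unknown reaction {rid!r}")
        c[ridx[rid]] = coef
    return c


def solve_lp(
    net: MetabolicNetwork,
    objective: dict[str, float],
    sense: str = "min",
    tol: float = LP_TOL,
) -> LPSolution:
    """Optimise a linear flux expression over the network polytope.

    Raises :class:`InfeasibleError` when the polytope is empty or the
    objective unbounded.
    """
    if sense not in ("min", "max"):
        raise ValueError(f"sense must be 'min' or 'max', got {sense!r}")
    c = _objective_vector(net, objective)
    sign = 1.0 if sense == "min" else -1.0
    S, _ = net.stoichiometric_matrix()
    lb, ub = net.bounds_arrays()
    A, b = net.inequality_arrays()
    res = linprog(
        sign * c,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        A_ub=A if A.shape[0] else None,
        b_ub=b if A.shape[0] else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if res.status != 0:
        raise InfeasibleError("linear programme failed", status=res.message)
    fluxes = pd.Series(res.x, index=net.reaction_ids)
    return LPSolution(float(sign * res.fun), fluxes, "optimal")


def assert_feasible(net: MetabolicNetwork, tol: float = LP_TOL) -> pd.Series:
    """Return one feasible flux vector, raising InfeasibleError if none exists."""
    return solve_lp(net, {net.reaction_ids[0]: 0.0}, "min", tol=tol).fluxes


def flux_violation(net: MetabolicNetwork, v: pd.Series) -> float:
    """Largest violation of mass balance, bounds or extra rows by ``v``."""
    x = v.reindex(net.reaction_ids).to_numpy(dtype=float)
    S, _ = net.stoichiometric_matrix()
    lb, ub = net.bounds_arrays()
    viol = 0.0
    if S.shape[0]:
        viol = float(np.max(np.abs(S @ x)))
    viol = max(viol, float(np.max(np.maximum(lb - x, 0), initial=0.0)))
    viol = max(viol, float(np.max(np.maximum(x - ub, 0), initial=0.0)))
    A, b = net.inequality_arrays()
    if A.shape[0]:
        viol = max(viol, float(np.max(np.maximum(A @ x - b, 0), initial=0.0)))
    return viol


# -- flux variability ------------------------------------------------------


def fva(
    net: MetabolicNetwork,
    objective: dict[str, float] | None = None,
    sense: str = "min",
    fraction_of_optimum: float | None = None,
    reactions: list[str] | None = None,
    tol: float = LP_TOL,
    return_solutions: bool = False,
):
    """Flux variability analysis: per-reaction min/max flux.

    When ``objective`` and ``fraction_of_optimum`` are given the polytope is
    first restricted to solutions within that fraction of the objective
    optimum — for a minimisation the constraint is ``c.v <= optimum /
    fraction`` (and ``optimum * fraction`` if the optimum is negative); for a
    maximisation ``c.v >= optimum * fraction``.

    Returns a DataFrame with columns ``minimum``/``maximum`` indexed by
    reaction id; with ``return_solutions=True`` also a list of the optimal
    flux vectors visited (useful to warm-start a sampler).
    """
    work = net
    if fraction_of_optimum is not None:
        if objective is None:
            raise ValueError("fraction_of_optimum requires an objective")
        if not 0 < fraction_of_optimum <= 1:
            raise ValueError("fraction_of_optimum must lie in (0, 1]")
        opt = solve_lp(net, objective, sense, tol=tol).objective_value
        work = net.copy()
        if sense == "min":
            bound = opt / fraction_of_optimum if opt >= 0 else opt * fraction_of_optimum
            work.inequalities.append((dict(objective), bound))
        else:
            bound = opt * fraction_of_optimum if opt >= 0 else opt / fraction_of_optimum
            work.inequalities.append(({k: -c for k, c in objective.items()}, -bound))
    targets = reactions if reactions is not None else work.reaction_ids
    rows, solutions = [], []
    for rid in targets:
        lo = solve_lp(work, {rid: 1.0}, "min", tol=tol)
        hi = solve_lp(work, {rid: 1.0}, "max", tol=tol)
        rows.append((rid, lo.objective_value, hi.objective_value))
        if return_solutions:
            solutions.extend([lo.fluxes, hi.fluxes])
    out = pd.DataFrame(rows, columns=["reaction", "minimum", "maximum"]).set_index("reaction")
    return (out, solutions) if return_solutions else out


@dataclass
class BlockedReport:
    """Outcome of the blocked-reaction check: per-reaction verdicts and the
    fraction of reactions able to carry flux above the threshold."""

    fraction_unblocked: float
    carries_flux: pd.Series
    threshold: float


def check_blocked(net: MetabolicNetwork, threshold: float = FEASIBILITY_TOL) -> BlockedReport:
    """Fraction of reactions able to carry |flux| > threshold somewhere in the
    feasible set — the standard model-validation figure for organ subnetworks."""
    ranges = fva(net)
    attainable = np.maximum(ranges["maximum"], -ranges["minimum"])
    verdict = attainable > threshold
    return BlockedReport(float(verdict.mean()), verdict, threshold)


def check_task(net: MetabolicNetwork, task: TaskSpec, input_bound: float = DEFAULT_BOUND) -> bool:
    """Can the network perform a metabolic task?

    All exchange reactions are closed, sources are opened for the task's
    allowed inputs, and each required output gets a sink with the required
    rate as lower bound; the task passes iff the resulting LP is feasible.
    """
    declared = set(net.metabolite_ids)
    unknown = (set(task.allowed_inputs) | set(task.required_outputs)) - declared
    if unknown:
        raise ValidationError(f"task {task.id!r} references unknown metabolites {sorted(unknown)}")
    work = net.copy()
    for r in work.reactions:
        if work.is_exchange(r):
            r.lb, r.ub = 0.0, 0.0
    for mid in sorted(task.allowed_inputs):
        work.reactions.append(
            Reaction(f"__task_in_{mid}", {mid: 1.0}, lb=0.0, ub=input_bound)
        )
    for mid, rate in task.required_outputs.items():
        work.reactions.append(
            Reaction(f"__task_out_{mid}", {mid: -1.0}, lb=rate, ub=input_bound + rate)
        )
    work.validate()
    try:
        assert_feasible(work)
        return True
    except InfeasibleError:
        return False


# -- network transformations ----------------------------------------------


def liftover_subnetwork(
    source_ids: set[str], id_map: dict[str, list[str] | str]
) -> tuple[set[str], set[str]]:
    """Map reaction ids between reconstructions.

    ``id_map`` maps a source id to one target id or a list of them (one-to-many
    entries are kept in full, with a warning).  Returns ``(mapped targets,
    unmapped source ids)``; the unmapped set is reported for manual curation.
    """
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for sid in source_ids:
        targets = id_map.get(sid)
        if targets is None:
            unmapped.add(sid)
            continue
        if isinstance(targets, str):
            targets = [targets]
        if len(targets) > 1:
            warnings.warn(f"one-to-many liftover for {sid!r}: keeping all of {sorted(targets)}")
        mapped.update(targets)
    return mapped, unmapped


def read_id_map(path) -> dict[str, list[str]]:
    """Read a two-column (source, target) TSV into a liftover map."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if tab.shape[1] < 2:
        raise ValidationError(f"id map {path} must have two columns")
    out: dict[str, list[str]] = {}
    for src, tgt in zip(tab.iloc[:, 0], tab.iloc[:, 1]):
        out.setdefault(src, []).append(tgt)
    return out


def assemble_organ_model(
    base: MetabolicNetwork,
    keep: set[str],
    exchange_bounds_a: dict[str, tuple[float, float]],
    exchange_bounds_b: dict[str, tuple[float, float]],
    boundary_compartments: set[str] = frozenset(),
) -> MetabolicNetwork:
    """Carve an organ subnetwork out of a base reconstruction.

    Keeps the ``keep`` reactions, sets each listed exchange bound to the
    arithmetic mean of the two parent (male/female whole-body) bounds — or the
    single parent's bounds when only one lists the reaction — flags
    metabolites in ``boundary_compartments`` (blood, bile, ...) as boundary,
    and drops metabolites no retained reaction references.
    """
    missing = set(keep) - set(base.reaction_ids)
    if missing:
        raise ValidationError(f"assemble: reactions absent from base network: {sorted(missing)}")
    reactions = []
    for r in base.reactions:
        if r.id not in keep:
            continue
        r = replace(r, stoich=dict(r.stoich))
        in_a, in_b = r.id in exchange_bounds_a, r.id in exchange_bounds_b
        if in_a and in_b:
            la, ua = exchange_bounds_a[r.id]
            lbb, ubb = exchange_bounds_b[r.id]
            r.lb, r.ub = (la + lbb) / 2.0, (ua + ubb) / 2.0
        elif in_a:
            r.lb, r.ub = exchange_bounds_a[r.id]
        elif in_b:
            r.lb, r.ub = exchange_bounds_b[r.id]
        reactions.append(r)
    used = {mid for r in reactions for mid in r.stoich}
    metabolites = [
        replace(m, boundary=m.boundary or m.compartment in boundary_compartments)
        for m in base.metabolites
        if m.id in used
    ]
    return MetabolicNetwork(metabolites, reactions, id=base.id)


def split_reversible(
    net: MetabolicNetwork, suffix: str = "_rev"
) -> tuple[MetabolicNetwork, dict[str, tuple[str, str | None]]]:
    """Replace reversible reactions by irreversible forward/reverse pairs.

    Every reaction with lb < 0 becomes a forward copy with bounds
    [0, max(ub, 0)] and a reverse copy with negated stoichiometry and bounds
    [0, -lb].  Returns the split network and a map
    ``original id -> (forward id, reverse id or None)`` so that net flux =
    forward − reverse is recoverable via :func:`recombine_fluxes`.

    After splitting, every flux is non-negative — the form required both by
    expression-weighted flux minimisation and by log transforms downstream.
    """
    reactions: list[Reaction] = []
    mapping: dict[str, tuple[str, str | None]] = {}
    for r in net.reactions:
        if r.lb >= 0:
            reactions.append(replace(r, stoich=dict(r.stoich)))
            mapping[r.id] = (r.id, None)
            continue
        fwd = replace(r, stoich=dict(r.stoich), lb=0.0, ub=max(r.ub, 0.0))
        rev = replace(
            r,
            id=r.id + suffix,
            name=r.name + " (reverse)",
            stoich={m: -c for m, c in r.stoich.items()},
            lb=0.0,
            ub=-r.lb,
        )
        reactions.extend([fwd, rev])
        mapping[r.id] = (fwd.id, rev.id)
    out = MetabolicNetwork([replace(m) for m in net.metabolites], reactions, id=net.id)
    return out, mapping


def recombine_fluxes(fluxes, mapping: dict[str, tuple[str, str | None]]):
    """Net fluxes (forward − reverse) of a split-network flux vector or matrix.

    Accepts a Series indexed by split reaction id, or a DataFrame with split
    reaction ids as columns.
    """
    if isinstance(fluxes, pd.DataFrame):
        data = {
            orig: (fluxes[f] - fluxes[r]) if r is not None else fluxes[f]
            for orig, (f, r) in mapping.items()
        }
        return pd.DataFrame(data)
    return pd.Series(
        {
            orig: (fluxes[f] - fluxes[r]) if r is not None else fluxes[f]
            for orig, (f, r) in mapping.items()
        }
    )
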