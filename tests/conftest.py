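"""Shared fixtures and independent oracles.

The vertex-enumeration oracle solves tiny flux polytopes exhaustively:
every vertex of {S v = 0, lb <= v <= ub, A v <= b} is the solution of a
square system built from the equality rows plus a choice of active bounds
or inequality rows.  Linear objectives attain their optima at vertices, so
min/max per coordinate gives FVA ranges and min of a weighted sum gives the
expression-weighted minimisation optimum — all without touching the LP code
under test.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from personaflux import Metabolite, MetabolicNetwork, Reaction, make_toy_network


def enumerate_vertices(net: MetabolicNetwork, tol: float = 1e-9) -> np.ndarray:
    S, _ = net.stoichiometric_matrix()
    lb, ub = net.bounds_arrays()
    A, b = net.inequality_arrays()
    n = len(net.reactions)
    candidates = []  # (row, rhs)
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        candidates.append((e, lb[i]))
        if ub[i] != lb[i]:
            candidates.append((e.copy(), ub[i]))
    for i in range(A.shape[0]):
        candidates.append((A[i], b[i]))
    rank_s = np.linalg.matrix_rank(S) if S.size else 0
    need = n - rank_s
    verts = []
    for combo in combinations(range(len(candidates)), need):
        rows = np.vstack([S] + [candidates[i][0] for i in combo]) if S.size else np.vstack(
            [candidates[i][0] for i in combo]
        )
        rhs = np.concatenate([np.zeros(S.shape[0]), [candidates[i][1] for i in combo]])
        if np.linalg.matrix_rank(rows) < n:
            continue
        v, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
        if np.max(np.abs(rows @ v - rhs)) > tol:
            continue
        feasible = (
            (v >= lb - 1e-7).all()
            and (v <= ub + 1e-7).all()
            and (S.size == 0 or np.max(np.abs(S @ v)) < 1e-7)
            and (A.shape[0] == 0 or (A @ v <= b + 1e-7).all())
        )
        if feasible:
            verts.append(np.clip(v, lb, ub))
    assert verts, "oracle found no vertices — polytope empty or unbounded?"
    uniq = []
    for v in verts:
        if not any(np.allclose(v, u, atol=1e-7) for u in uniq):
            uniq.append(v)
    return np.array(uniq)


def oracle_fva(net: MetabolicNetwork) -> pd.DataFrame:
    verts = enumerate_vertices(net)
    return pd.DataFrame(
        {"minimum": verts.min(axis=0), "maximum": verts.max(axis=0)},
        index=net.reaction_ids,
    )


def oracle_weighted_min(net: MetabolicNetwork, weights: pd.Series) -> float:
    verts = enumerate_vertices(net)
    w = weights.reindex(net.reaction_ids).fillna(1.0).to_numpy(dtype=float)
    return float((verts @ w).min())


@pytest.fixture
def toy3():
    return make_toy_network("toy3")


@pytest.fixture
def branched6():
    return make_toy_network("branched6")


@pytest.fixture
def reversible4():
    return make_toy_network("reversible4")


@pytest.fixture
def toy3_profile():
    # g3 lowly expressed so R3 carries a large minimisation weight
    return pd.Series({"g1": 10.0, "g2a": 3.0, "g2b": 5.0, "g3": 1.0})


@pytest.fixture
def dead_end_network():
    # R2 produces B which nothing consumes: R2 is blocked
    mets = [Metabolite("A", "c"), Metabolite("B", "c")]
    rxns = [
        Reaction("R1", {"A": 1.0}, 0, 10),
        Reaction("R2", {"A": -1.0, "B": 1.0}, 0, 10),
        Reaction("R3", {"A": -1.0}, 0, 10),
    ]
    return MetabolicNetwork(mets, rxns, id="deadend")
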