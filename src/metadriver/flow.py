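"""Network-flow ILP linking a mutant gene to signature TFs over a weighted PPI.

A dummy source s is attached to the mutant gene and a dummy sink t to every
target TF, both through weight-0 edges. Binary node variables x_i, binary
edge variables y_ij and integer flows z_ij encode the selection of a
connected subnetwork: R+1 flow units leave s, each selected node consumes
one unit, flow travels only on selected edges, s and t keep degree ≥ 1 and
every selected internal node degree ≥ 2. The objective maximizes the summed
Pearson edge weight of the selected edges minus a sparsity penalty λ per
internal edge. The upper bound R caps the number of selected network nodes.

After solving, all simple mutant→TF paths inside the selected subgraph are
scored by the mean edge weight Pw = Σ w_i / n; a mutant gene's score is its
maximum Pw, and mutants are ranked by that score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .expression import pairwise_pearson

logger = logging.getLogger(__name__)

_S = "__source__"
_T = "__sink__"


def weight_network(
    ppi: nx.Graph, expr_hrm: pd.DataFrame, absolute: bool = False
) -> nx.Graph:
    """Pearson-weight the PPI on HRM expression; drop unmeasured endpoints.

    Edges with an endpoint absent from the expression matrix, or with an
    undefined correlation (zero variance), are removed; the drop count is
    stored as graph attribute ``n_dropped_edges``. Weights are signed
    correlations by default; ``absolute=True`` uses |r| instead.
    """
    if expr_hrm.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = expr_hrm.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    genes = [g for g, v in zip(expr_hrm.index, variable) if v]
    measured = set(genes)
    common = measured & set(ppi.nodes)
    if not common:
        raise ValueError("no overlap between PPI nodes and measured genes")
    pos = {g: i for i, g in enumerate(genes)}
    r, _ = pairwise_pearson(values[variable])
    out = nx.Graph()
    out.add_nodes_from(sorted(common))
    n_dropped = 0
    for a, b in ppi.edges:
        if a in pos and b in pos:
            w = float(r[pos[a], pos[b]])
            out.add_edge(a, b, weight=abs(w) if absolute else w)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%d PPI edges dropped (unmeasured or zero-variance endpoint)", n_dropped)
    out.graph["n_dropped_edges"] = n_dropped
    return out


@dataclass
class FlowProgram:
    """The ILP instance for one mutant gene against a TF sink set."""

    network: nx.Graph
    mutant: str
    tfs: tuple[str, ...]
    R: int = 20
    lambda_flow: float = 0.01
    size_mode: str = "atmost"  # "atmost": ≤ R nodes; "exact": exactly R
    infeasible_by_construction: bool = field(default=False)
    reason: str = ""


def build_flow_program(
    net: nx.Graph,
    mutant: str,
    tfs,
    R: int = 20,
    lambda_flow: float = 0.01,
    size_mode: str = "atmost",
) -> FlowProgram:
    """Assemble the flow ILP for *mutant* against the TF set *tfs*.

    A mutant absent from the network, or a TF set with no member in the
    network, yields a program flagged infeasible by construction (the
    interactome simply does not connect them).
    """
    if size_mode not in ("atmost", "exact"):
        raise ValueError("size_mode must be 'atmost' or 'exact'")
    tfs = tuple(sorted(set(tfs)))
    if not tfs:
        raise ValueError("TF set must be nonempty")
    present_tfs = tuple(f for f in tfs if f in net)
    fp = FlowProgram(net, mutant, present_tfs, R, lambda_flow, size_mode)
    if mutant not in net:
        fp.infeasible_by_construction = True
        fp.reason = f"mutant {mutant!r} not in network"
    elif not present_tfs:
        fp.infeasible_by_construction = True
        fp.reason = "no TF present in network"
    elif net.degree(mutant) == 0 and mutant not in present_tfs:
        fp.infeasible_by_construction = True
        fp.reason = f"mutant {mutant!r} is isolated"
    return fp


@dataclass
class PathwayResult:
    mutant_gene: str
    feasible: bool
    selected_nodes: tuple[str, ...] = ()
    selected_edges: tuple[tuple[str, str, float], ...] = ()
    reached_tfs: tuple[str, ...] = ()
    best_path: tuple[str, ...] = ()
    Pw: float = float("nan")
    objective: float = float("nan")
    reason: str = ""


def _solve_ilp(fp: FlowProgram):
    """Encode and solve the MILP; return (selected nodes, edges, objective)."""
    net, mutant, tfs, R, lam = fp.network, fp.mutant, fp.tfs, fp.R, fp.lambda_flow
    nodes = sorted(net.nodes)
    nidx = {v: i for i, v in enumerate(nodes)}
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    # dummy edges: (s, mutant) and (tf, t) for each TF, weight 0
    dummy_edges = [(_S, mutant)] + [(f, _T) for f in tfs]
    all_edges = edges + dummy_edges
    eidx = {frozenset(e): k for k, e in enumerate(all_edges)}
    # directed arcs carrying flow: both directions for network edges,
    # s -> mutant, tf -> t (no flow into s, none out of t)
    arcs = []
    for a, b in edges:
        arcs.append((a, b))
        arcs.append((b, a))
    arcs.append((_S, mutant))
    for f in tfs:
        arcs.append((f, _T))
    aidx = {arc: k for k, arc in enumerate(arcs)}

    nx_ = len(nodes)
    ny = len(all_edges)
    nz = len(arcs)
    nvar = nx_ + ny + nz
    X = lambda v: nidx[v]
    Y = lambda e: nx_ + eidx[frozenset(e)]
    Z = lambda a: nx_ + ny + aidx[a]

    cost = np.zeros(nvar)
    for a, b in edges:  # maximize Σ(w − λ)·y over internal edges
        cost[Y((a, b))] = -(net.edges[a, b]["weight"] - lam)

    rows, lo, hi = [], [], []

    def add(coefs: dict[int, float], lb: float, ub: float) -> None:
        r = np.zeros(nvar)
        for k, c in coefs.items():
            r[k] += c
        rows.append(r); lo.append(lb); hi.append(ub)

    cap = R + 1
    # y_e ≤ x endpoint (x_s = x_t = 1 are constants)
    for e in all_edges:
        for v in e:
            if v not in (_S, _T):
                add({Y(e): 1.0, X(v): -1.0}, -np.inf, 0.0)
    # degree: s and t ≥ 1; internal nodes Σ y ≥ 2 x_i
    add({Y((_S, mutant)): 1.0}, 1.0, np.inf)
    add({Y((f, _T)): 1.0 for f in tfs}, 1.0, np.inf)
    for v in nodes:
        coefs = {X(v): -2.0}
        for u in net[v]:
            coefs[Y((u, v))] = coefs.get(Y((u, v)), 0.0) + 1.0
        if v == mutant:
            coefs[Y((_S, mutant))] = coefs.get(Y((_S, mutant)), 0.0) + 1.0
        if v in tfs:
            coefs[Y((v, _T))] = coefs.get(Y((v, _T)), 0.0) + 1.0
        add(coefs, 0.0, np.inf)
    # source flow: R+1 units leave s (exact) or at most R+1 (upper-bound size)
    if fp.size_mode == "exact":
        add({Z((_S, mutant)): 1.0}, cap, cap)
    else:
        add({Z((_S, mutant)): 1.0}, 0.0, cap)
    # conservation: inflow − outflow = x_j for j ∈ V, = 1 for t
    for v in nodes:
        coefs: dict[int, float] = {X(v): -1.0}
        for u in net[v]:
            coefs[Z((u, v))] = coefs.get(Z((u, v)), 0.0) + 1.0
            coefs[Z((v, u))] = coefs.get(Z((v, u)), 0.0) - 1.0
        if v == mutant:
            coefs[Z((_S, mutant))] = coefs.get(Z((_S, mutant)), 0.0) + 1.0
        if v in tfs:
            coefs[Z((v, _T))] = coefs.get(Z((v, _T)), 0.0) - 1.0
        add(coefs, 0.0, 0.0)
    add({Z((f, _T)): 1.0 for f in tfs}, 1.0, 1.0)
    # capacity: inflow into j ≤ (R+1)·x_j
    for v in nodes:
        coefs = {X(v): -float(cap)}
        for u in net[v]:
            coefs[Z((u, v))] = coefs.get(Z((u, v)), 0.0) + 1.0
        if v == mutant:
            coefs[Z((_S, mutant))] = coefs.get(Z((_S, mutant)), 0.0) + 1.0
        add(coefs, -np.inf, 0.0)
    # flow only on selected edges: z_uv + z_vu ≤ (R+1)·y_e
    for a, b in edges:
        add({Z((a, b)): 1.0, Z((b, a)): 1.0, Y((a, b)): -float(cap)}, -np.inf, 0.0)
    add({Z((_S, mutant)): 1.0, Y((_S, mutant)): -float(cap)}, -np.inf, 0.0)
    for f in tfs:
        add({Z((f, _T)): 1.0, Y((f, _T)): -float(cap)}, -np.inf, 0.0)
    # size bound Σ x ≤ R (implied by flow accounting; stated for strength)
    add({X(v): 1.0 for v in nodes}, -np.inf, float(R))

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    ub[nx_ + ny:] = cap  # integer flows in [0, R+1]
    res = milp(
        c=cost,
        constraints=[LinearConstraint(np.array(rows), lo, hi)],
        bounds=Bounds(lb, ub),
        integrality=np.ones(nvar),
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise RuntimeError(f"flow MILP failed: {res.message}")
    xsol = res.x
    sel_nodes = tuple(v for v in nodes if xsol[X(v)] > 0.5)
    sel_edges = tuple(
        (a, b, float(net.edges[a, b]["weight"]))
        for a, b in edges
        if xsol[Y((a, b))] > 0.5
    )
    return sel_nodes, sel_edges, -float(res.fun)


def solve_pathway(fp: FlowProgram) -> PathwayResult:
    """Solve the flow ILP and score the best mutant→TF path by mean weight.

    The selected subgraph (dummy nodes stripped) is searched for all simple
    paths from the mutant to each reached TF of length ≤ R edges; each path
    is scored by Pw = mean edge weight and the maximum is reported.
    """
    if fp.infeasible_by_construction:
        return PathwayResult(fp.mutant, False, reason=fp.reason)
    solved = _solve_ilp(fp)
    if solved is None:
        return PathwayResult(fp.mutant, False, reason="ILP infeasible")
    sel_nodes, sel_edges, objective = solved
    sub = nx.Graph()
    sub.add_nodes_from(sel_nodes)
    for a, b, w in sel_edges:
        sub.add_edge(a, b, weight=w)
    if fp.mutant not in sub:
        return PathwayResult(fp.mutant, False, reason="mutant not selected")
    reached = tuple(
        f for f in fp.tfs if f in sub and nx.has_path(sub, fp.mutant, f)
    )
    if not reached:
        return PathwayResult(fp.mutant, False, reason="no TF reachable in selection")
    best_path: tuple[str, ...] = ()
    best_pw = -np.inf
    for f in reached:
        if f == fp.mutant:
            continue
        for path in nx.all_simple_paths(sub, fp.mutant, f, cutoff=fp.R):
            weights = [sub.edges[u, v]["weight"] for u, v in zip(path, path[1:])]
            pw = float(np.mean(weights))
            if pw > best_pw + 1e-12 or (
                abs(pw - best_pw) <= 1e-12 and tuple(path) < best_path
            ):
                best_pw, best_path = pw, tuple(path)
    if not best_path:
        # mutant is itself the only reached TF: trivial pathway, no edges
        return PathwayResult(
            fp.mutant, True, tuple(sel_nodes), sel_edges, reached,
            (fp.mutant,), float("nan"), objective,
        )
    return PathwayResult(
        fp.mutant, True, tuple(sel_nodes), sel_edges, reached,
        best_path, best_pw, objective,
    )


def rank_mutants(results) -> pd.DataFrame:
    """Rank feasible mutants by descending maximum pathway weight Pw.

    Ties break lexicographically by gene symbol. Infeasible results are
    dropped. Returns a DataFrame with columns ``gene`` and ``Pw``.
    """
    rows = [
        (r.mutant_gene, r.Pw)
        for r in results
        if r.feasible and np.isfinite(r.Pw)
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["gene", "Pw"])
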