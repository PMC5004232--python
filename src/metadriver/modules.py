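"""Co-expression network, greedy cohesiveness modules, TF/DEG enrichment.

The high-risk-group co-expression network links two genes when their Pearson
correlation exceeds ``r_min`` with p-value below ``p_max``. Modules are
detected by greedy growth of the cohesiveness score

    f(V) = w_in / (w_in + w_bound + penalty·|V|)

with edge weight equal to the correlation r, following the ClusterONE
procedure (seed at the heaviest unassigned node, grow/shrink to a local
maximum, merge highly overlapping candidates, discard small or sparse ones).
Over-representation of DEGs and TF target sets in a module is assessed with
the hypergeometric upper tail. Modules enriched for DEGs and for at least
one TF's targets are the network signatures; those TFs are the flow stage's
sink set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .expression import pairwise_pearson

logger = logging.getLogger(__name__)


def build_coexpression_network(
    expr_hrm: pd.DataFrame, r_min: float = 0.7, p_max: float = 0.01
) -> nx.Graph:
    """Pairwise-correlation graph over the genes of an expression matrix.

    *expr_hrm* is genes × samples (HRM samples only, by convention). Genes
    with zero variance are excluded with a warning. Each edge stores the
    correlation as both ``r`` and ``weight``. The correlation threshold is
    strict (r > r_min), except that perfect correlation (r = 1) always
    qualifies, so r_min = 1.0 links exactly the collinear pairs.
    """
    if expr_hrm.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = expr_hrm.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.warning("%d zero-variance genes excluded from co-expression", n_dropped)
    genes = [g for g, v in zip(expr_hrm.index, variable) if v]
    r, p = pairwise_pearson(values[variable])
    graph = nx.Graph(r_min=r_min, p_max=p_max, n_dropped_genes=n_dropped)
    graph.add_nodes_from(genes)
    passes = ((r > r_min) | (r >= 1.0 - 1e-12)) & (p < p_max)
    ii, jj = np.where(np.triu(passes, k=1))
    for i, j in zip(ii, jj):
        graph.add_edge(genes[i], genes[j], r=float(r[i, j]), weight=float(r[i, j]))
    return graph


@dataclass
class GeneModule:
    """A co-expressed gene set with quality and enrichment annotations."""

    genes: frozenset[str]
    cohesiveness: float
    density: float
    deg_enrichment_p: float | None = None
    tf_enrichment: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def _cohesiveness(graph: nx.Graph, nodes: set[str], penalty: float) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, data in graph[u].items():
            w = data.get("weight", 1.0)
            if v in nodes:
                w_in += w / 2.0
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def _density(graph: nx.Graph, nodes: set[str]) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    edges = sum(1 for u in nodes for v in graph[u] if v in nodes) // 2
    return 2.0 * edges / (k * (k - 1))


def _grow_module(graph: nx.Graph, seed: str, penalty: float) -> set[str]:
    """Greedy local maximization of cohesiveness from a single seed node."""
    current = {seed}
    score = _cohesiveness(graph, current, penalty)
    while True:
        best_change, best_score = None, score
        boundary = sorted({v for u in current for v in graph[u] if v not in current})
        for v in boundary:
            s = _cohesiveness(graph, current | {v}, penalty)
            if s > best_score + 1e-12:
                best_change, best_score = ("add", v), s
        for v in sorted(current - {seed}):
            s = _cohesiveness(graph, current - {v}, penalty)
            if s > best_score + 1e-12:
                best_change, best_score = ("remove", v), s
        if best_change is None:
            return current
        op, v = best_change
        current = current | {v} if op == "add" else current - {v}
        score = best_score


def _overlap_score(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_modules(
    net: nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    min_density: float = 0.5,
    overlap_max: float = 0.8,
) -> list[GeneModule]:
    """ClusterONE-style greedy cohesiveness clustering.

    Seeds are taken in decreasing order of total incident edge weight among
    nodes not yet assigned to a candidate module; each candidate is grown to
    a local cohesiveness maximum, highly overlapping candidates
    (|A∩B|²/(|A||B|) ≥ *overlap_max*) are merged, and candidates below
    *min_size* or *min_density* are discarded. Deterministic given the
    canonical (lexicographic) node order.
    """
    if net.number_of_nodes() == 0:
        return []
    weight = {
        u: sum(d.get("weight", 1.0) for d in net[u].values()) for u in net.nodes
    }
    assigned: set[str] = set()
    candidates: list[frozenset[str]] = []
    for seed in sorted(net.nodes, key=lambda u: (-weight[u], u)):
        if seed in assigned or weight[seed] <= 0:
            continue
        module = _grow_module(net, seed, penalty)
        candidates.append(frozenset(module))
        assigned |= module

    # iterative merge of highly overlapping candidates
    merged = True
    while merged:
        merged = False
        out: list[frozenset[str]] = []
        for cand in candidates:
            for k, existing in enumerate(out):
                if _overlap_score(cand, existing) >= overlap_max:
                    out[k] = existing | cand
                    merged = True
                    break
            else:
                out.append(cand)
        candidates = out

    modules = []
    for genes in candidates:
        if len(genes) < min_size:
            continue
        dens = _density(net, set(genes))
        if dens < min_density:
            continue
        modules.append(
            GeneModule(genes, _cohesiveness(net, set(genes), penalty), dens)
        )
    modules.sort(key=lambda m: (-len(m.genes), tuple(sorted(m.genes))))
    return modules


def enrichment_p(module_genes: set, annotated_genes: set, universe: set) -> float:
    """Hypergeometric upper-tail P(X ≥ overlap) of a module/annotation overlap.

    Population = *universe*, successes = annotated genes, draws = module
    size. Both gene sets must be subsets of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes)
    annotated_genes = set(annotated_genes)
    if not module_genes <= set(universe) or not annotated_genes <= set(universe):
        raise ValueError("module and annotation must be subsets of the universe")
    k = len(module_genes & annotated_genes)
    return float(
        stats.hypergeom.sf(k - 1, len(universe), len(annotated_genes), len(module_genes))
    )


@dataclass
class SignatureSet:
    """DEG-enriched modules with their enriched regulating TFs."""

    modules: list[GeneModule]
    tfs: set[str]


def select_signatures(
    modules: list[GeneModule],
    degs: pd.DataFrame,
    tfmap: dict[str, frozenset[str]],
    universe: set[str],
    p_threshold: float = 0.01,
) -> SignatureSet:
    """Keep modules enriched for DEGs and for ≥1 TF's targets; collect the TFs.

    Both enrichments use the hypergeometric upper tail against *universe*
    (the measured genes). TF target sets are intersected with the universe
    before testing.
    """
    deg_set = set(degs.index[degs["deg"]]) & set(universe)
    selected, tfs = [], set()
    for module in modules:
        genes = set(module.genes) & set(universe)
        module.deg_enrichment_p = enrichment_p(genes, deg_set, universe)
        module.tf_enrichment = {}
        for tf, targets in tfmap.items():
            targets_u = set(targets) & set(universe)
            if not targets_u:
                continue
            module.tf_enrichment[tf] = enrichment_p(genes, targets_u, universe)
        enriched_tfs = {
            tf for tf, p in module.tf_enrichment.items() if p < p_threshold
        }
        if module.deg_enrichment_p < p_threshold and enriched_tfs:
            selected.append(module)
            tfs |= enriched_tfs
    if not selected:
        logger.warning("no signature modules: downstream flow stage has no targets")
    return SignatureSet(selected, tfs)


class CoexpressionModuleDetector(BaseEstimator):
    """Scikit-learn style wrapper: fit(X) on samples × genes expression.

    Builds the thresholded correlation network and detects cohesive modules.

    Attributes
    ----------
    network_ : the thresholded co-expression graph
    modules_ : list of :class:`GeneModule`
    labels_ : per-gene module index (−1 for unassigned; first module wins
        for genes in several modules)
    """

    def __init__(
        self,
        r_min: float = 0.7,
        p_max: float = 0.01,
        penalty: float = 2.0,
        min_size: int = 3,
        min_density: float = 0.5,
        overlap_max: float = 0.8,
    ):
        self.r_min = r_min
        self.p_max = p_max
        self.penalty = penalty
        self.min_size = min_size
        self.min_density = min_density
        self.overlap_max = overlap_max

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        expr = X.T  # genes × samples
        expr.index = [str(g) for g in expr.index]
        self.network_ = build_coexpression_network(expr, self.r_min, self.p_max)
        self.modules_ = detect_modules(
            self.network_,
            penalty=self.penalty,
            min_size=self.min_size,
            min_density=self.min_density,
            overlap_max=self.overlap_max,
        )
        labels = np.full(X.shape[1], -1, dtype=int)
        gene_pos = {str(g): i for i, g in enumerate(X.columns)}
        for k, module in enumerate(self.modules_):
            for g in module.genes:
                if labels[gene_pos[g]] == -1:
                    labels[gene_pos[g]] = k
        self.labels_ = labels
        return self
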