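"""Metabolite-metabolite correlation network: Spearman matrix, top-K edge
selection, density scan, eigenvector-centrality ranking and export.

The network uses the K unordered metabolite pairs with the largest absolute
Spearman rank correlation (computed over pooled control + treated study
samples on normalized, unscaled metabolite levels).  Candidate K values are
scanned for the K minimising network density 2E / (N (N-1)), where N counts
only nodes incident to a selected edge.  Nodes are ranked by eigenvector
centrality of the unweighted adjacency (a |rho|-weighted variant is
available), rescaled so the maximum score is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "MetaboliteNetwork",
    "CentralityRanking",
    "spearman_matrix",
    "select_top_k",
    "scan_density",
    "eigenvector_centrality",
    "export_network",
    "DEFAULT_K_VALUES",
]

DEFAULT_K_VALUES = tuple(range(10, 85, 5))


@dataclass
class CorrelationResult:
    scc: pd.DataFrame          # metabolites x metabolites, NaN for excluded
    p_values: pd.DataFrame
    n_samples: int
    excluded: list[str]        # constant metabolites (undefined rho)


def spearman_matrix(levels: pd.DataFrame) -> CorrelationResult:
    """All-pairs Spearman correlation with two-sided t-approximation p-values.

    The coefficient is the Pearson correlation of mid-ranks (average ranks
    for ties); p-values use t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees
    of freedom.  Constant metabolites have undefined rho and are excluded
    (recorded, with a warning).
    """
    n, m = levels.shape
    if n < 4:
        raise ValueError("at least 4 samples required")
    if m < 2:
        raise ValueError("at least 2 metabolites required")

    ranks = levels.rank(axis=0, method="average")
    sd = ranks.std(axis=0, ddof=1)
    excluded = list(levels.columns[sd == 0])
    if excluded:
        warnings.warn(f"{len(excluded)} constant metabolite(s) excluded from "
                      f"correlation ranking: {excluded}", stacklevel=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks.to_numpy(dtype=float), rowvar=False)
    rho = pd.DataFrame(rho, index=levels.columns, columns=levels.columns)
    rho.loc[excluded, :] = np.nan
    rho.loc[:, excluded] = np.nan
    for c in levels.columns:
        if c not in excluded:
            rho.loc[c, c] = 1.0

    r = rho.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 0.0, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    pdf = pd.DataFrame(p, index=levels.columns, columns=levels.columns)
    return CorrelationResult(scc=rho, p_values=pdf, n_samples=n,
                             excluded=excluded)


@dataclass
class MetaboliteNetwork:
    graph: nx.Graph
    k_requested: int
    edges: pd.DataFrame        # source, target, scc, p_value, rank

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        n, e = self.n_nodes, self.n_edges
        return 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")


def _ranked_pairs(corr: CorrelationResult) -> list[tuple]:
    cols = [c for c in corr.scc.columns if c not in set(corr.excluded)]
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            lo, hi = sorted((a, b))
            pairs.append((lo, hi, float(corr.scc.loc[a, b]),
                          float(corr.p_values.loc[a, b])))
    # highest |rho| first; deterministic lexicographic tie-break
    pairs.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return pairs


def select_top_k(corr: CorrelationResult, k: int) -> MetaboliteNetwork:
    """Network of the K pairs with the largest |Spearman rho|.

    Boundary ties are broken by the lexicographic order of the sorted
    metabolite-name pair; nodes are the incident metabolites only.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    pairs = _ranked_pairs(corr)
    if not pairs:
        raise ValueError("no metabolite pairs available")
    if k > len(pairs):
        warnings.warn(f"K={k} exceeds the {len(pairs)} available pairs; "
                      "selecting all", stacklevel=2)
    chosen = pairs[:k]
    g = nx.Graph()
    rows = []
    for rank, (a, b, r, p) in enumerate(chosen, start=1):
        g.add_edge(a, b, scc=r, p_value=p, rank=rank)
        rows.append({"source": a, "target": b, "scc": r,
                     "p_value": p, "rank": rank})
    edges = pd.DataFrame(rows, columns=["source", "target", "scc",
                                        "p_value", "rank"])
    return MetaboliteNetwork(graph=g, k_requested=k, edges=edges)


def scan_density(corr: CorrelationResult,
                 k_values=DEFAULT_K_VALUES) -> tuple[pd.DataFrame, int]:
    """Density of the top-K network over candidate K values.

    Returns the scan table (K, n_nodes, n_edges, density) and the K with the
    lowest density (smallest K on ties).
    """
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be non-empty")
    if any(b <= a for a, b in zip(k_values, k_values[1:])):
        raise ValueError("k_values must be strictly ascending")
    rows = []
    best_k, best_d = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in k_values:
            net = select_top_k(corr, k)
            d = net.density
            rows.append({"K": k, "n_nodes": net.n_nodes,
                         "n_edges": net.n_edges, "density": d})
            if d < best_d:
                best_k, best_d = k, d
    return pd.DataFrame(rows), int(best_k)


@dataclass
class CentralityRanking:
    scores: pd.Series          # per node, max = 1
    in_dominant: pd.Series     # bool: inside the dominant component

    def top(self, n: int = 5) -> pd.Series:
        return self.scores.sort_values(ascending=False).head(n)


def _power_iteration(a: np.ndarray, x0: np.ndarray, tol: float,
                     max_iter: int) -> np.ndarray | None:
    x = x0 / np.linalg.norm(x0)
    for _ in range(max_iter):
        x1 = a @ x
        n = np.linalg.norm(x1)
        if n == 0:
            return None
        x1 /= n
        if np.linalg.norm(x1 - x) < tol:
            return x1
        x = x1
    return None


def eigenvector_centrality(network: MetaboliteNetwork,
                           weighted: bool = False, tol: float = 1e-10,
                           max_iter: int = 10000) -> CentralityRanking:
    """Eigenvector-centrality scores via power iteration, rescaled to max 1.

    The default adjacency is unweighted; ``weighted=True`` uses |rho| edge
    weights.  Power iteration starts from the all-ones vector; if it fails
    to converge (oscillation on a bipartite dominant component), it restarts
    from 1 + 1e-3 * degree on the diagonally shifted adjacency A + I, which
    has the same eigenvectors but a strictly dominant eigenvalue.  Nodes
    with a score below 1e-6 are flagged as outside the dominant component.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes,
                          weight="scc" if weighted else None)
    if weighted:
        a = np.abs(a)

    x = _power_iteration(a, np.ones(len(nodes)), tol, max_iter)
    if x is None:
        deg = a.sum(axis=1)
        shifted = a + np.eye(len(nodes))
        x = _power_iteration(shifted, 1.0 + 1e-3 * deg, tol, max_iter)
        if x is None:
            raise RuntimeError("eigenvector centrality failed to converge")
    x = np.abs(x)
    x = x / x.max()
    scores = pd.Series(x, index=nodes, name="ec_score")
    return CentralityRanking(scores=scores, in_dominant=scores >= 1e-6)


def export_network(network: MetaboliteNetwork, ranking: CentralityRanking,
                   sif_path, graphml_path) -> None:
    """Write the network as SIF and GraphML (Cytoscape-ready).

    The SIF file has one ``metabolite <tab> cc <tab> metabolite`` line per
    edge (in rank order).  The GraphML file carries scc/p_value/rank edge
    attributes and ec_score/in_dominant node attributes, with names escaped
    per XML rules.
    """
    try:
        with open(sif_path, "w") as fh:
            for _, e in network.edges.iterrows():
                fh.write(f"{e['source']}\tcc\t{e['target']}\n")
    except OSError as err:
        raise OSError(f"failed to write SIF file {sif_path}: {err}") from err

    g = nx.Graph()
    for node in network.graph.nodes:
        g.add_node(node, ec_score=float(ranking.scores[node]),
                   in_dominant=bool(ranking.in_dominant[node]))
    for _, e in network.edges.iterrows():
        g.add_edge(e["source"], e["target"], scc=float(e["scc"]),
                   p_value=float(e["p_value"]), rank=int(e["rank"]))
    try:
        nx.write_graphml(g, graphml_path)
    except OSError as err:
        raise OSError(
            f"failed to write GraphML file {graphml_path}: {err}") from err
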