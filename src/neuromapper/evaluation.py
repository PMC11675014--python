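"""Shape-graph validation and goodness-of-fit.

Validation asks whether a shape graph is non-degenerate at all, via three
criteria: coverage (beta, percent of time points in the largest connected
component), autocorrelation content (alpha, percent of nodes whose member
time span exceeds the hemodynamic threshold tau), and structural
complexity (S, Shannon entropy of the inter-node hop-distance histogram).

Goodness-of-fit then asks whether a *valid* graph has the right topology:
for circular-trajectory data the "circleness" criterion (stable-low and
stable-high states joined by a transition-up-only arc and a
transition-down-only arc), and for task-paradigm data the average delay
between changepoints of the normalized degree and the expected transition
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .shapegraph import ShapeGraph

__all__ = [
    "ValidationReport", "GOFResult", "STATE_ORDER",
    "validate", "circleness", "detect_transitions", "average_delay",
]

#: Fixed state vocabulary of the simulated circular trajectory; the order
#: doubles as the tie-break for majority node labeling.
STATE_ORDER = ("stable-low", "transition-up", "stable-high", "transition-down")


@dataclass
class ValidationReport:
    beta: float                 # % points in largest connected component
    alpha: float                # % nodes spanning more than tau seconds
    entropy: float              # S, bits
    tau: float = 11.0
    alpha_min: float = 15.0
    beta_min: float = 70.0
    s_min: float = 2.0
    valid: bool = False

    def __post_init__(self) -> None:
        self.valid = (self.alpha >= self.alpha_min and
                      self.beta > self.beta_min and
                      self.entropy >= self.s_min)


@dataclass
class GOFResult:
    circleness: bool | None = None
    transitions: list[float] = field(default_factory=list)   # seconds
    average_delay: float = float("inf")
    delta: float = 12.0
    passed: bool = False

    def __post_init__(self) -> None:
        self.passed = self.average_delay <= self.delta


def _hop_entropy(graph: ShapeGraph, component: list[int]) -> float:
    """Base-2 Shannon entropy of the unit-width histogram of pairwise
    shortest-path hop distances between the component's node pairs."""
    if len(component) < 2:
        return 0.0
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import shortest_path as sp_hops
    pos = {nid: i for i, nid in enumerate(component)}
    comp_set = set(component)
    rows, cols = [], []
    for a, b in graph.edges:
        if a in comp_set and b in comp_set:
            rows.append(pos[a])
            cols.append(pos[b])
    m = len(component)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    H = sp_hops(adj.tocsr(), method="D", directed=False, unweighted=True)
    hops = H[np.triu_indices(m, 1)].astype(int)
    c = np.bincount(hops)[1:].astype(float)  # unit-width integer bins
    c = c[c > 0]
    p = c / c.sum()
    return float(-(p * np.log2(p)).sum())


def validate(graph: ShapeGraph, tr: float, tau: float = 11.0,
             alpha_min: float = 15.0, beta_min: float = 70.0,
             s_min: float = 2.0) -> ValidationReport:
    """Compute the alpha/beta/S validation report for a shape graph.

    beta: 100 x (members of the largest connected component) / N.
    alpha: 100 x (nodes whose temporal span (max-min index) x tr exceeds
    tau seconds) / (number of nodes).
    S: hop-distance entropy of the largest component; a single-node graph
    scores 0.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot validate a graph with zero nodes")
    comp = graph.largest_component()
    comp_members = np.unique(np.concatenate(
        [graph.members(i) for i in comp]))
    beta = 100.0 * comp_members.size / graph.n_points
    spans = np.array([(graph.members(i).max() - graph.members(i).min()) * tr
                      for i in range(graph.n_nodes)])
    alpha = 100.0 * float(np.count_nonzero(spans > tau)) / graph.n_nodes
    S = _hop_entropy(graph, comp)
    return ValidationReport(beta=beta, alpha=alpha, entropy=S, tau=tau,
                            alpha_min=alpha_min, beta_min=beta_min, s_min=s_min)


def label_nodes(graph: ShapeGraph, labels: np.ndarray) -> list[str]:
    """Majority state per node; ties resolved by the fixed STATE_ORDER."""
    labels = np.asarray(labels)
    if len(labels) != graph.n_points:
        raise ValueError(
            f"labels length {len(labels)} != n_points {graph.n_points}")
    out = []
    for node in graph.nodes:
        states, counts = np.unique(labels[node["members"]], return_counts=True)
        # earliest state in the fixed order wins ties
        best = min(states[counts == counts.max()],
                   key=lambda s: STATE_ORDER.index(s) if s in STATE_ORDER else 99)
        out.append(str(best))
    return out


def _arc_exists(G: nx.Graph, node_states: dict[int, str], lo: str, hi: str,
                interior: str) -> bool:
    """Is there a lo-to-hi path whose interior nodes are all ``interior``,
    with at least one interior node?  Checked on the subgraph of
    {lo, hi, interior}-labeled nodes via interior connectivity."""
    interior_nodes = [n for n, s in node_states.items() if s == interior]
    if not interior_nodes:
        return False
    lo_nodes = {n for n, s in node_states.items() if s == lo}
    hi_nodes = {n for n, s in node_states.items() if s == hi}
    if not lo_nodes or not hi_nodes:
        return False
    # connected components of the interior-only subgraph; an arc exists iff
    # some component touches both a lo node and a hi node
    sub = G.subgraph(interior_nodes)
    for comp in nx.connected_components(sub):
        touches_lo = any(G.has_edge(u, v) for u in comp for v in lo_nodes)
        touches_hi = any(G.has_edge(u, v) for u in comp for v in hi_nodes)
        if touches_lo and touches_hi:
            return True
    return False


def circleness(graph: ShapeGraph, labels: np.ndarray,
               strict: bool = False) -> bool:
    """Does the shape graph realize the circular state trajectory?

    Nodes are majority-labeled; the graph minus transition-down nodes must
    contain a stable-low -> stable-high path whose interior is pure
    transition-up (at least one interior node), and symmetrically for the
    transition-down arc with transition-up nodes removed.  ``strict``
    additionally fails graphs with a direct stable-low/stable-high edge.
    """
    node_states = dict(enumerate(label_nodes(graph, labels)))
    G = graph.to_networkx()
    up = _arc_exists(G, node_states, "stable-low", "stable-high", "transition-up")
    down = _arc_exists(G, node_states, "stable-low", "stable-high", "transition-down")
    ok = up and down
    if strict and ok:
        lo = [n for n, s in node_states.items() if s == "stable-low"]
        hi = [n for n, s in node_states.items() if s == "stable-high"]
        if any(G.has_edge(u, v) for u in lo for v in hi):
            ok = False
    return ok


def detect_transitions(degree: np.ndarray, n_change: int,
                       tr: float = 1.0) -> list[float]:
    """Exact changepoints of the piecewise-constant-mean model.

    Finds the ``n_change`` changepoints minimizing the total within-segment
    squared error by dynamic programming (globally optimal, not a
    heuristic).  A changepoint at sample ``c`` starts a new segment at
    ``c``; returned as times ``c * tr`` in seconds.
    """
    y = np.asarray(degree, dtype=float)
    T = y.size
    if n_change < 1:
        raise ValueError("n_change must be >= 1")
    if T < n_change + 1:
        raise ValueError(f"series length {T} too short for {n_change} changepoints")
    if np.allclose(y, y[0]):
        raise ValueError("constant series has no detectable changepoints")
    # segment cost via cumulative sums: cost[a, b) = sum (y - mean)^2
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        n = b - a
        s = c1[b] - c1[a]
        q = c2[b] - c2[a]
        return q - s * s / n

    K = n_change + 1  # number of segments
    # dp[k][t] = min cost of fitting y[0:t] with k segments; arg[k][t] the
    # start of the optimal last segment
    dp = np.full((K + 1, T + 1), np.inf)
    arg = np.zeros((K + 1, T + 1), dtype=int)
    dp[0][0] = 0.0
    for k in range(1, K + 1):
        for t in range(k, T + 1):
            a = np.arange(k - 1, t)
            cand = dp[k - 1][a] + seg_cost(a, t)
            best = int(np.argmin(cand))
            dp[k][t], arg[k][t] = cand[best], a[best]
    # backtrack: segment starts other than 0 are the changepoints
    cps = []
    t = T
    for k in range(K, 0, -1):
        t = int(arg[k][t])
        if k > 1:
            cps.append(t)
    cps.sort()
    return [float(c * tr) for c in cps]


def average_delay(extracted: list[float], expected: list[float]) -> float:
    """Mean absolute gap between each EXPECTED transition and its nearest
    extracted one (missed transitions inflate the delay); empty extraction
    returns +inf."""
    expected = list(expected)
    if not expected:
        raise ValueError("expected transition list must be nonempty")
    if not extracted:
        return float("inf")
    ex = np.asarray(extracted, dtype=float)
    return float(np.mean([np.min(np.abs(ex - e)) for e in expected]))
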