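"""Hierarchical scale-free networks with tunable rich-club connectivity.

The graph family is the deterministic clique-replication construction of
Ravasz and Barabási: a complete 5-clique is replicated and the peripheral
nodes of the replicas are wired back to a central hub, once per hierarchy
step.  Five step-2 units (125 nodes each) are assembled into a 625-node
network whose 25 hubs (5 global, 20 local — 4% of the nodes) are then
interconnected pairwise with probability ``kappa``, the rich-club strength.

Neurons are typed excitatory/inhibitory under Dale's law: every outgoing
link of a neuron carries the sign of that neuron.  Global hubs are all
inhibitory (case 1) or all excitatory (case 2); each local hub is
inhibitory with probability ``eta``; of the remaining nodes exactly 80%
are excitatory and 20% inhibitory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "HierarchicalNetwork",
    "build_base_network",
    "assemble_replicas",
    "classify_hubs",
    "connect_rich_club",
    "assign_neuron_types",
    "normalized_rich_club",
    "variant_unidirectional",
    "variant_randomize_keep_indegree",
    "degree_exponent",
    "degree_exponent_ml",
    "write_network",
    "read_network",
]

HUB_NONE = "none"
HUB_LOCAL = "local"
HUB_GLOBAL = "global"

EXC = "excitatory"
INH = "inhibitory"

#: module (clique) size of the construction; every hierarchy step multiplies
#: the node count by this factor.
BRANCHING = 5


@dataclass
class HierarchicalNetwork:
    """Directed signed graph with hierarchy, hub and neuron-type annotations.

    ``edges`` holds directed links as an ``(E, 2)`` integer array of
    ``(source, target)`` rows; in bidirectional mode every undirected edge
    is present once per direction.  The link sign is a *node* property
    (Dale's law): all outgoing links of neuron ``i`` carry
    ``+1`` if ``neuron_type[i]`` is excitatory and ``-1`` otherwise.
    """

    n_nodes: int
    edges: np.ndarray
    cluster5: np.ndarray
    cluster25: np.ndarray
    cluster125: np.ndarray
    hub_class: np.ndarray
    neuron_type: np.ndarray = field(default=None)  # type: ignore[assignment]
    bidirectional: bool = True

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.neuron_type is None:
            self.neuron_type = np.full(self.n_nodes, "", dtype="U10")

    # -- derived quantities -------------------------------------------------

    def undirected_pairs(self) -> set[tuple[int, int]]:
        """Set of undirected node pairs with at least one link."""
        return {(min(s, t), max(s, t)) for s, t in self.edges}

    @property
    def degree(self) -> np.ndarray:
        """Undirected degree of every node."""
        k = np.zeros(self.n_nodes, dtype=np.int64)
        for a, b in self.undirected_pairs():
            k[a] += 1
            k[b] += 1
        return k

    @property
    def hubs(self) -> np.ndarray:
        return np.flatnonzero(self.hub_class != HUB_NONE)

    @property
    def is_excitatory(self) -> np.ndarray:
        if np.any(self.neuron_type == ""):
            raise ValueError("neuron types not assigned yet")
        return self.neuron_type == EXC

    def link_sign(self) -> np.ndarray:
        """Per-edge sign (+1/-1), inherited from the source neuron."""
        sign = np.where(self.is_excitatory, 1, -1)
        return sign[self.edges[:, 0]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.undirected_pairs())
        return g

    def copy(self) -> "HierarchicalNetwork":
        return replace(
            self,
            edges=self.edges.copy(),
            cluster5=self.cluster5.copy(),
            cluster25=self.cluster25.copy(),
            cluster125=self.cluster125.copy(),
            hub_class=self.hub_class.copy(),
            neuron_type=self.neuron_type.copy(),
        )


def _both_directions(pairs: "list[tuple[int, int]] | set[tuple[int, int]]") -> np.ndarray:
    arr = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return np.vstack([arr, arr[:, ::-1]])


def _clique_pairs(nodes: list[int]) -> list[tuple[int, int]]:
    return list(itertools.combinations(nodes, 2))


def build_base_network(steps: int) -> HierarchicalNetwork:
    """Build the deterministic clique-replication network.

    ``steps=1`` gives 25 nodes: five complete 5-cliques, with the four
    peripheral nodes of each replica clique (positions 1–4; position 0 is
    the replica's own centre and stays unwired) linked to node 0, the hub.
    ``steps=2`` replicates the 25-node unit four more times and wires the
    16 outer peripheral nodes of each replica unit to node 0, which becomes
    the global hub (degree 84); the four replica-unit hubs (nodes 25, 50,
    75, 100) are the local hubs (degree 20).
    """
    if steps not in (1, 2):
        raise ValueError(f"steps must be 1 or 2, got {steps!r}")

    pairs: list[tuple[int, int]] = []
    # step 1: five 5-cliques; peripherals (q>=1, p>=1) attach to hub 0
    for q in range(5):
        pairs += _clique_pairs([5 * q + p for p in range(5)])
    pairs += [(0, 5 * q + p) for q in range(1, 5) for p in range(1, 5)]

    if steps == 2:
        unit = list(pairs)
        pairs = []
        for u in range(5):
            pairs += [(25 * u + a, 25 * u + b) for a, b in unit]
        # outer peripherals of each replica unit attach to the global hub
        pairs += [
            (0, 25 * u + 5 * q + p)
            for u in range(1, 5)
            for q in range(1, 5)
            for p in range(1, 5)
        ]

    n = 25 if steps == 1 else 125
    ids = np.arange(n)
    hub_class = np.full(n, HUB_NONE, dtype="U10")
    if steps == 1:
        hub_class[0] = HUB_LOCAL
    else:
        hub_class[0] = HUB_GLOBAL
        hub_class[[25, 50, 75, 100]] = HUB_LOCAL

    return HierarchicalNetwork(
        n_nodes=n,
        edges=_both_directions(pairs),
        cluster5=ids // 5,
        cluster25=ids // 25,
        cluster125=ids // 125,
        hub_class=hub_class,
    )


def assemble_replicas(unit: HierarchicalNetwork, n_replicas: int = 5) -> HierarchicalNetwork:
    """Disjoint union of ``n_replicas`` copies of a step-2 unit.

    No edges are added between replicas: inter-replica connectivity comes
    only from the subsequent rich-club wiring of hub pairs.
    """
    if unit.n_nodes != 125:
        raise ValueError("assemble_replicas expects a step-2 (125-node) unit")
    if n_replicas != 5:
        raise ValueError("the assembly uses exactly 5 replicas")

    n = unit.n_nodes * n_replicas
    ids = np.arange(n)
    edges = np.vstack([unit.edges + r * unit.n_nodes for r in range(n_replicas)])
    hub_class = np.concatenate([unit.hub_class] * n_replicas)
    return HierarchicalNetwork(
        n_nodes=n,
        edges=edges,
        cluster5=ids // 5,
        cluster25=ids // 25,
        cluster125=ids // 125,
        hub_class=hub_class,
    )


def classify_hubs(net: HierarchicalNetwork) -> np.ndarray:
    """Recompute hub labels from construction role and check degree ranges.

    Classification is structural: the top node of each 125-node unit is a
    global hub, the four intermediate unit hubs are local.  The degree
    windows quoted for the two classes (local 20–44; global >= 80 before
    rich-club wiring) are asserted as construction invariants, not used to
    classify.
    """
    ids = np.arange(net.n_nodes)
    hub_class = np.full(net.n_nodes, HUB_NONE, dtype="U10")
    if net.n_nodes == 25:
        hub_class[0] = HUB_LOCAL
    else:
        hub_class[(ids % 125 == 0)] = HUB_GLOBAL
        hub_class[(ids % 25 == 0) & (ids % 125 != 0)] = HUB_LOCAL

    k = net.degree
    if np.any(k[hub_class == HUB_GLOBAL] < 80):
        raise AssertionError("global hub degree below 80: construction bug")
    loc = k[hub_class == HUB_LOCAL]
    if loc.size and (loc.min() < 20 or loc.max() > 44):
        raise AssertionError("local hub degree outside [20, 44]: construction bug")
    return hub_class


def connect_rich_club(
    net: HierarchicalNetwork, kappa: float, rng: np.random.Generator
) -> HierarchicalNetwork:
    """Wire each non-adjacent hub pair bidirectionally with probability kappa.

    All hub pairs are eligible — global–global, global–local and
    local–local, across replicas.  Pairs already adjacent from the base
    construction are skipped (re-adding them would create multi-edges).
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    out = net.copy()
    hubs = net.hubs
    existing = net.undirected_pairs()
    eligible = [p for p in itertools.combinations(sorted(hubs), 2) if p not in existing]
    if not eligible:
        return out
    keep = rng.random(len(eligible)) < kappa
    new = [p for p, k in zip(eligible, keep) if k]
    if new:
        out.edges = np.vstack([out.edges, _both_directions(new)])
    return out


def assign_neuron_types(
    net: HierarchicalNetwork,
    case: int,
    eta: float,
    rng: np.random.Generator,
    local_hub_inhibitory: "list[int] | None" = None,
) -> HierarchicalNetwork:
    """Assign excitatory/inhibitory types.

    Global hubs are all inhibitory (case 1) or all excitatory (case 2).
    Each local hub is independently inhibitory with probability ``eta``
    unless ``local_hub_inhibitory`` pins an explicit set of local-hub node
    ids.  Non-hubs are split exactly 80% excitatory / 20% inhibitory,
    chosen uniformly at random.
    """
    if case not in (1, 2):
        raise ValueError(f"case must be 1 or 2, got {case!r}")
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")

    out = net.copy()
    types = np.full(net.n_nodes, EXC, dtype="U10")
    types[net.hub_class == HUB_GLOBAL] = INH if case == 1 else EXC

    local = np.flatnonzero(net.hub_class == HUB_LOCAL)
    if local_hub_inhibitory is not None:
        bad = set(local_hub_inhibitory) - set(local.tolist())
        if bad:
            raise ValueError(f"not local hubs: {sorted(bad)}")
        types[list(local_hub_inhibitory)] = INH
    else:
        types[local[rng.random(local.size) < eta]] = INH

    non_hubs = np.flatnonzero(net.hub_class == HUB_NONE)
    n_inh = round(0.2 * non_hubs.size)
    types[rng.choice(non_hubs, size=n_inh, replace=False)] = INH

    out.neuron_type = types
    return out


def normalized_rich_club(
    net: HierarchicalNetwork,
    k_values: np.ndarray,
    n_null: int = 100,
    rng: "np.random.Generator | None" = None,
    swaps_per_edge: int = 10,
) -> dict[int, float]:
    """Normalized rich-club coefficient Phi_norm(k).

    For each degree threshold ``k``: the number of undirected edges among
    nodes of degree > k, divided by the mean of the same count over
    ``n_null`` degree-preserving randomizations (double-edge swaps).
    Thresholds with no qualifying node pair give NaN.  Phi_norm > 1 marks
    genuine rich-club organization.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    g = net.to_networkx()
    deg = dict(g.degree())
    nswap = swaps_per_edge * g.number_of_edges()

    def club_edges(graph: nx.Graph, k: int) -> int:
        rich = [n for n in graph if deg[n] > k]
        return graph.subgraph(rich).number_of_edges()

    null_counts = {int(k): [] for k in k_values}
    for _ in range(n_null):
        h = g.copy()
        nx.double_edge_swap(h, nswap=nswap, max_tries=50 * nswap,
                            seed=int(rng.integers(2**31)))
        # degrees are preserved by the swap, so `deg` stays valid for h
        for k in null_counts:
            null_counts[k].append(club_edges(h, k))

    phi: dict[int, float] = {}
    for k in null_counts:
        obs = club_edges(g, k)
        mean_null = float(np.mean(null_counts[k]))
        phi[k] = float("nan") if mean_null == 0 else obs / mean_null
    return phi


def variant_unidirectional(
    net: HierarchicalNetwork, rng: np.random.Generator
) -> HierarchicalNetwork:
    """Keep exactly one randomly chosen direction per undirected edge."""
    out = net.copy()
    pairs = np.array(sorted(net.undirected_pairs()), dtype=np.int64)
    flip = rng.random(len(pairs)) < 0.5
    out.edges = np.where(flip[:, None], pairs[:, ::-1], pairs)
    out.bidirectional = False
    return out


def variant_randomize_keep_indegree(
    net: HierarchicalNetwork, rng: np.random.Generator
) -> HierarchicalNetwork:
    """Redraw every incoming link's source uniformly, preserving indegrees.

    Destroys the hierarchical/cluster structure while keeping each node's
    number of incoming links; self-loops are resampled away.
    """
    out = net.copy()
    edges = net.edges.copy()
    src = rng.integers(0, net.n_nodes, size=len(edges))
    clash = src == edges[:, 1]
    while np.any(clash):
        src[clash] = rng.integers(0, net.n_nodes, size=int(clash.sum()))
        clash = src == edges[:, 1]
    edges[:, 0] = src
    out.edges = edges
    out.bidirectional = False
    return out


# -- degree-distribution exponent ------------------------------------------


def degree_exponent_ml(
    degrees: np.ndarray, k_min_grid: "np.ndarray | None" = None
) -> tuple[float, int]:
    """Discrete maximum-likelihood power-law fit with KS-selected cutoff.

    For each candidate lower cutoff ``k_min`` the exponent of
    ``P(k) ~ k**-gamma`` on ``k >= k_min`` is estimated by maximizing the
    zeta-normalized discrete likelihood; the cutoff minimizing the
    Kolmogorov–Smirnov distance between data and fit is retained.
    Returns ``(gamma, k_min)``.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    degrees = np.asarray(degrees)
    if k_min_grid is None:
        k_min_grid = np.unique(degrees)[:-1]

    best = (np.inf, np.nan, 0)
    for k_min in k_min_grid:
        tail = degrees[degrees >= k_min]
        if tail.size < 2:
            continue
        log_sum = np.log(tail).sum()

        def nll(g: float) -> float:
            return tail.size * np.log(zeta(g, k_min)) + g * log_sum

        res = minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
        gamma = float(res.x)
        ks = np.arange(k_min, tail.max() + 1)
        pmf = ks.astype(float) ** -gamma / zeta(gamma, k_min)
        cdf_model = np.cumsum(pmf)
        cdf_data = np.searchsorted(np.sort(tail), ks, side="right") / tail.size
        d = np.abs(cdf_data - cdf_model).max()
        if d < best[0]:
            best = (d, gamma, int(k_min))
    return best[1], best[2]


def degree_exponent(degrees: np.ndarray, tail_fraction: float = 0.05) -> tuple[float, int]:
    """Exponent of P(k) ~ k**-gamma from a survival-function tail fit.

    The cutoff ``k_min`` is the smallest distinct degree whose survival
    probability P(K >= k) does not exceed ``tail_fraction`` (default: the
    top 5% of nodes, which for the hierarchical construction is exactly
    its hub hierarchy — hubs are 4% of nodes).  ``gamma`` is then
    ``1 - slope`` of the least-squares line through ``log P(K >= k)``
    versus ``log k`` over the distinct degrees of the tail.  Returns
    ``(gamma, k_min)``.

    Deterministic hierarchical graphs concentrate their degrees on a few
    discrete levels (the homogeneous clique bulk plus one hub level per
    hierarchy step), which biases pmf-based maximum-likelihood estimators
    far above the family exponent; the survival-function slope across hub
    levels recovers it.
    """
    degrees = np.asarray(degrees)
    uniq = np.unique(degrees)
    n = degrees.size
    ccdf_all = np.array([(degrees >= k).sum() / n for k in uniq])
    in_tail = ccdf_all <= tail_fraction
    # need at least two distinct degree levels to fit a slope
    while in_tail.sum() < 2 and not in_tail.all():
        in_tail[np.flatnonzero(~in_tail)[-1]] = True
    if in_tail.sum() < 2:
        raise ValueError("degree distribution has fewer than two distinct values")
    ks_vals = uniq[in_tail]
    slope = np.polyfit(np.log(ks_vals), np.log(ccdf_all[in_tail]), 1)[0]
    return float(1.0 - slope), int(ks_vals[0])


# -- serialization ----------------------------------------------------------


def write_network(net: HierarchicalNetwork, outdir: "str | Path") -> None:
    """Write edge list (``src  dst  sign``) and node attribute table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    typed = not np.any(net.neuron_type == "")
    sign = net.link_sign() if typed else np.ones(len(net.edges), dtype=int)
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("src\tdst\tsign\n")
        for (s, t), g in zip(net.edges, sign):
            fh.write(f"{s}\t{t}\t{g:+d}\n")
    k = net.degree
    with open(outdir / "nodes.tsv", "w") as fh:
        fh.write("node\tdegree\thub_class\tneuron_type\tcluster5\tcluster25\tcluster125\n")
        for i in range(net.n_nodes):
            fh.write(
                f"{i}\t{k[i]}\t{net.hub_class[i]}\t{net.neuron_type[i] or 'unassigned'}"
                f"\t{net.cluster5[i]}\t{net.cluster25[i]}\t{net.cluster125[i]}\n"
            )


def read_network(indir: "str | Path") -> HierarchicalNetwork:
    indir = Path(indir)
    edges = np.loadtxt(indir / "edges.tsv", skiprows=1, usecols=(0, 1), dtype=np.int64, ndmin=2)
    rows = np.loadtxt(indir / "nodes.tsv", skiprows=1, dtype=str, ndmin=2)
    n = rows.shape[0]
    types = rows[:, 3].astype("U10")
    types[types == "unassigned"] = ""
    return HierarchicalNetwork(
        n_nodes=n,
        edges=edges,
        cluster5=rows[:, 4].astype(np.int64),
        cluster25=rows[:, 5].astype(np.int64),
        cluster125=rows[:, 6].astype(np.int64),
        hub_class=rows[:, 2].astype("U10"),
        neuron_type=types,
    )
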