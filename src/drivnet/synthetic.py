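"""Synthetic study-condition generators.

Three generators cover the inputs the pipeline consumes:

* ``make_scale_free`` — a preferential-attachment (Barabasi-Albert) gene
  network emulating the heavy-tailed degree distribution of protein
  interaction networks;
* ``make_structural_twins`` — a graph with two disjoint isomorphic
  components plus a sparse random component, with the known automorphic
  counterpart pairs (far apart yet structurally identical) returned as
  ground truth for structural-embedding properties;
* ``simulate_cohort`` — a planted-driver binary mutation cohort: a chosen
  driver gene set mutates at rate ``p_driver`` per sample, every other gene
  at the passenger rate ``p_passenger``.

Drivers are planted as a connected module by default because the
framework's premise is that diffusion amplifies functionally clustered
mutation signal; ``driver_placement="random"`` is the hard-mode control.
All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .net_io import BenchmarkGeneSet, GeneNetwork, MutationMatrix

__all__ = [
    "PlantedCohort",
    "make_scale_free",
    "make_structural_twins",
    "simulate_cohort",
    "make_recovery_cohort",
    "RECOVERY_DEFAULTS",
]

# default planted-driver study conditions (desk scale: full pipeline in minutes)
RECOVERY_DEFAULTS = dict(
    n_genes=300,
    n_samples=120,
    n_drivers=25,
    p_driver=0.25,
    p_passenger=0.03,
    attachment=2,
)


@dataclass
class PlantedCohort:
    net: GeneNetwork
    mat: MutationMatrix
    drivers: BenchmarkGeneSet
    params: dict

    def __post_init__(self) -> None:
        if not self.drivers.genes <= self.net.nodes:
            raise ValueError("drivers must be network nodes")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def make_scale_free(n_genes: int, attachment: int, seed: int) -> GeneNetwork:
    """Connected preferential-attachment graph with (n - m) * m edges."""
    if attachment < 1 or n_genes < attachment + 1:
        raise ValueError("need n_genes >= attachment + 1 and attachment >= 1")
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=seed)
    return GeneNetwork.from_edges((_gene_name(a), _gene_name(b)) for a, b in g.edges())


def _twin_template(n: int = 10) -> nx.Graph:
    """Threshold graph: vertices added alternately dominating/isolated.

    Degrees are pairwise distinct except one tie, so the graph is
    essentially asymmetric: the counterpart list returned by
    ``make_structural_twins`` captures the structurally identical pairs
    instead of being diluted by internal symmetries (a clique or barbell
    template would contain large automorphism classes). Its degree range
    also exceeds the sparse random component's, which keeps template nodes
    from having near-equivalents there.
    """
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        g.add_node(v)
        if v % 2 == 1:
            g.add_edges_from((v, u) for u in range(v))
    return g


def make_structural_twins(seed: int = 0) -> tuple[GeneNetwork, list[tuple[str, str]]]:
    """Two disjoint isomorphic components plus a sparse random component.

    Returns the network and the automorphic counterpart pairs: node TA_i of
    the first copy and TB_i of the second are at infinite graph distance
    but structurally identical, so their structural distance is 0 at every
    layer and a structural embedding must place them close together.
    """
    template = _twin_template()
    edges: list[tuple[str, str]] = []
    for prefix in ("TA", "TB"):
        edges += [(f"{prefix}_{a}", f"{prefix}_{b}") for a, b in template.edges()]
    rng_graph = nx.gnm_random_graph(15, 22, seed=seed)
    # keep the random part one component so it contributes varied structures
    comps = list(nx.connected_components(rng_graph))
    order = sorted(comps, key=len, reverse=True)
    for prev, nxt in zip(order, order[1:]):
        rng_graph.add_edge(min(prev), min(nxt))
    edges += [(f"R_{a}", f"R_{b}") for a, b in rng_graph.edges()]
    net = GeneNetwork.from_edges(edges)
    pairs = [(f"TA_{i}", f"TB_{i}") for i in template.nodes()]
    return net, pairs


def simulate_cohort(
    net: GeneNetwork,
    n_samples: int,
    n_drivers: int,
    p_driver: float,
    p_passenger: float,
    driver_placement: str = "module",
    seed: int = 0,
) -> PlantedCohort:
    """Planted-driver binary mutation cohort on a given gene network."""
    if not (0 <= p_passenger < p_driver < 1):
        raise ValueError("need 0 <= p_passenger < p_driver < 1")
    if n_drivers >= net.n_nodes:
        raise ValueError("n_drivers must be smaller than the gene universe")
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    if driver_placement == "module":
        g = net.to_networkx()
        # grow a connected neighborhood from a random seed gene (BFS order)
        start = genes[int(rng.integers(len(genes)))]
        drivers: list[str] = []
        for node in nx.bfs_tree(g, start):
            drivers.append(node)
            if len(drivers) == n_drivers:
                break
        if len(drivers) < n_drivers:  # small component: top up uniformly
            rest = [x for x in genes if x not in set(drivers)]
            extra = rng.choice(len(rest), size=n_drivers - len(drivers), replace=False)
            drivers += [rest[i] for i in sorted(extra)]
    elif driver_placement == "random":
        idx = rng.choice(len(genes), size=n_drivers, replace=False)
        drivers = [genes[i] for i in sorted(idx)]
    else:
        raise ValueError("driver_placement must be 'module' or 'random'")
    driver_set = frozenset(drivers)
    rates = np.array([p_driver if g_ in driver_set else p_passenger for g_ in genes])
    values = (rng.random((n_samples, len(genes))) < rates).astype(np.int8)
    mat = MutationMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        gene_ids=list(genes),
        values=values,
    )
    return PlantedCohort(
        net=net,
        mat=mat,
        drivers=BenchmarkGeneSet(name="planted", genes=driver_set),
        params=dict(
            n_genes=net.n_nodes, n_samples=n_samples, n_drivers=n_drivers,
            p_driver=p_driver, p_passenger=p_passenger,
            driver_placement=driver_placement, seed=seed,
        ),
    )


def make_recovery_cohort(seed: int = 0) -> PlantedCohort:
    """The default planted-driver recovery fixture (see RECOVERY_DEFAULTS)."""
    p = RECOVERY_DEFAULTS
    net = make_scale_free(p["n_genes"], p["attachment"], seed=seed)
    return simulate_cohort(
        net, n_samples=p["n_samples"], n_drivers=p["n_drivers"],
        p_driver=p["p_driver"], p_passenger=p["p_passenger"],
        driver_placement="module", seed=seed + 1,
    )
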