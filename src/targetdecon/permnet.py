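"""Interaction-network enrichment of regulated protein sets.

Given a differential table and a physical-interaction database, tests
whether the regulated proteins are more interconnected than a random
protein set of the same size: the database is filtered to one organism and
a whitelist of direct physical-evidence types, the induced subgraph of the
regulated set is extracted, and its node and edge counts are compared
against sets sampled uniformly from the database universe.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionDb",
    "RegulatedSet",
    "NetworkTestResult",
    "DEFAULT_SYSTEMS",
    "filter_interactions",
    "regulated_set",
    "induced_stats",
    "permutation_test",
    "exact_test",
]

#: Direct physical-interaction evidence types accepted by default
#: (proximity-labeling and co-fractionation evidence is excluded).
DEFAULT_SYSTEMS = frozenset(
    {"Affinity Capture-Western", "Co-purification", "Affinity Capture-MS"}
)


@dataclasses.dataclass
class InteractionDb:
    """Deduplicated undirected interaction network with provenance."""

    graph: nx.Graph
    provenance: dict

    @property
    def node_universe(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> dict[str, set[str]]:
        return {n: set(self.graph.neighbors(n)) for n in self.graph.nodes}


@dataclasses.dataclass
class RegulatedSet:
    """Proteins passing differential thresholds, matched against a database."""

    proteins: set[str]
    lfc_cut: float
    padj_cut: float
    n_in_db: int
    unmatched: tuple[str, ...] = ()


@dataclasses.dataclass
class NetworkTestResult:
    """Observed induced-subgraph statistics and permutation p values.

    ``p_*_raw`` follow the count/B convention (can be exactly 0, matching
    how permutation results are often printed); ``p_*_cons`` use the
    add-one (count+1)/(B+1) estimator which is never 0.
    """

    n_connected: int
    n_edges: int
    b: int
    p_nodes_raw: float
    p_edges_raw: float
    p_nodes_cons: float
    p_edges_cons: float
    seed: int


def _norm_symbol(s) -> str:
    return str(s).strip().upper()


def filter_interactions(
    raw_edges: pd.DataFrame,
    organism: int = 9606,
    systems: Iterable[str] = DEFAULT_SYSTEMS,
    known_systems: Iterable[str] | None = None,
) -> InteractionDb:
    """Filter an annotated (TAB3-style) edge table to a simple graph.

    Records are kept when both interactors belong to ``organism`` and the
    experimental system is in the ``systems`` whitelist; unordered duplicate
    pairs collapse to one edge and self-loops are dropped. A minimal
    two-column edge list (no annotations) is accepted as already filtered.
    The node universe is the set of endpoints of the retained edges.
    """
    systems = set(systems)
    if known_systems is not None:
        unknown = systems - set(known_systems)
        if unknown:
            warnings.warn(f"unrecognized evidence codes in whitelist: {sorted(unknown)}")

    cols = set(raw_edges.columns)
    if {"Official Symbol Interactor A", "Official Symbol Interactor B"} <= cols:
        col_a, col_b = "Official Symbol Interactor A", "Official Symbol Interactor B"
    else:
        col_a, col_b = raw_edges.columns[:2]

    df = raw_edges.copy()
    n_raw = len(df)
    if {"Organism ID Interactor A", "Organism ID Interactor B"} <= cols:
        df = df[
            (df["Organism ID Interactor A"].astype(int) == organism)
            & (df["Organism ID Interactor B"].astype(int) == organism)
        ]
    if "Experimental System" in cols:
        df = df[df["Experimental System"].isin(systems)]

    g = nx.Graph()
    for a, b in zip(df[col_a].map(_norm_symbol), df[col_b].map(_norm_symbol)):
        if a != b:
            g.add_edge(a, b)
    return InteractionDb(
        graph=g,
        provenance={
            "organism": organism,
            "systems": sorted(systems),
            "n_records_in": n_raw,
            "n_records_kept": int(len(df)),
            "n_edges": g.number_of_edges(),
            "n_nodes": g.number_of_nodes(),
        },
    )


def regulated_set(
    diff_table: pd.DataFrame,
    lfc_cut: float = 0.25,
    padj_cut: float = 0.05,
    db: InteractionDb | None = None,
) -> RegulatedSet:
    """Extract the regulated protein set from a differential table.

    Members satisfy |log2FC| > ``lfc_cut`` (strict) AND adjusted
    p < ``padj_cut`` (strict). Expected columns: an identifier column
    (first non-numeric or named protein/entity/gene), ``log2fc``, ``padj``.
    """
    df = diff_table
    id_col = next(
        (c for c in ("protein", "entity", "gene") if c in df.columns), df.columns[0]
    )
    sel = (df["log2fc"].abs() > lfc_cut) & (df["padj"] < padj_cut)
    members = {_norm_symbol(x) for x in df.loc[sel, id_col]}
    unmatched: tuple[str, ...] = ()
    n_in_db = len(members)
    if db is not None:
        universe = db.node_universe
        unmatched = tuple(sorted(members - universe))
        n_in_db = len(members & universe)
    return RegulatedSet(
        proteins=members,
        lfc_cut=lfc_cut,
        padj_cut=padj_cut,
        n_in_db=n_in_db,
        unmatched=unmatched,
    )


def induced_stats(db: InteractionDb, node_set: Iterable[str]) -> tuple[int, int, int]:
    """(n_in_db, n_connected, n_edges) of the subgraph induced by a set.

    ``n_edges`` counts edges with both endpoints in the set; ``n_connected``
    counts set members with at least one such edge. Members absent from the
    node universe contribute nothing.
    """
    nodes = {_norm_symbol(n) for n in node_set}
    present = nodes & db.node_universe
    sub = db.graph.subgraph(present)
    n_edges = sub.number_of_edges()
    n_connected = sum(1 for n in present if sub.degree(n) > 0)
    return len(present), n_connected, n_edges


def _sample_stats(adj: Mapping[str, set], sample: Sequence[str]) -> tuple[int, int]:
    s = set(sample)
    n_edges = 0
    n_connected = 0
    for u in s:
        d = len(adj[u] & s)
        n_edges += d
        if d:
            n_connected += 1
    return n_connected, n_edges // 2


def permutation_test(
    db: InteractionDb,
    k: int,
    observed: tuple[int, int],
    b: int = 10_000,
    seed: int = 0,
    tail: str = "ge",
) -> NetworkTestResult:
    """Permutation null for induced-subgraph connectivity.

    Draws ``b`` uniform samples of ``k`` distinct nodes from the database
    universe and counts how often the sampled induced subgraph reaches the
    observed connected-node and edge counts. ``tail='ge'`` (default) counts
    samples with statistic ≥ observed; ``'gt'`` uses strict >.
    """
    universe = sorted(db.node_universe)
    if k > len(universe):
        raise ValueError("k exceeds the node universe size")
    obs_nodes, obs_edges = observed
    adj = db.adjacency()
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe, dtype=object)

    cnt_nodes = cnt_edges = 0
    for _ in range(b):
        idx = rng.choice(len(universe_arr), size=k, replace=False)
        n_conn, n_edg = _sample_stats(adj, universe_arr[idx])
        if tail == "gt":
            cnt_nodes += n_conn > obs_nodes
            cnt_edges += n_edg > obs_edges
        else:
            cnt_nodes += n_conn >= obs_nodes
            cnt_edges += n_edg >= obs_edges
    return NetworkTestResult(
        n_connected=obs_nodes,
        n_edges=obs_edges,
        b=b,
        p_nodes_raw=cnt_nodes / b,
        p_edges_raw=cnt_edges / b,
        p_nodes_cons=(cnt_nodes + 1) / (b + 1),
        p_edges_cons=(cnt_edges + 1) / (b + 1),
        seed=seed,
    )


def exact_test(
    db: InteractionDb,
    k: int,
    observed: tuple[int, int],
    tail: str = "ge",
    max_subsets: int = 10**6,
) -> tuple[float, float]:
    """Exact tail probabilities by complete subset enumeration.

    Serves as the enumeration oracle for :func:`permutation_test` on small
    graphs; refuses when C(|universe|, k) exceeds ``max_subsets``.
    Returns (p_nodes, p_edges).
    """
    universe = sorted(db.node_universe)
    n = len(universe)
    if k > n:
        raise ValueError("k exceeds the node universe size")
    total = math.comb(n, k)
    if total > max_subsets:
        raise ValueError(f"C({n},{k}) = {total} exceeds the enumeration bound")
    obs_nodes, obs_edges = observed
    adj = db.adjacency()
    cnt_nodes = cnt_edges = 0
    for subset in itertools.combinations(universe, k):
        n_conn, n_edg = _sample_stats(adj, subset)
        if tail == "gt":
            cnt_nodes += n_conn > obs_nodes
            cnt_edges += n_edg > obs_edges
        else:
            cnt_nodes += n_conn >= obs_nodes
            cnt_edges += n_edg >= obs_edges
    return cnt_nodes / total, cnt_edges / total
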