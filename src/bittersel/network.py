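"""Median-joining haplotype networks and four-gamete recombination scans.

The median-joining construction follows Bandelt's scheme: distinct
haplotypes are condensed, an epsilon-relaxed minimum spanning network (MSN)
is built over them, consensus ("median vector") haplotypes of linked triples
are added while they reduce the connection cost, and finally median vectors
that no longer shorten the network are pruned.  Indel polymorphisms are
coded as single events (a contiguous gap run is one character) and weighted
twice as much as substitutions by default.

The four-gamete scan flags site pairs exhibiting all four gametes — under
infinite sites these require recombination (or recurrent mutation) — and
localizes a single crossover to the interval between the closest
incompatible pair flanking the compatible core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .io import INDEL, MISSING, SUBSTITUTION, HaplotypeAlignment, PopulationMap

__all__ = ["MJNetwork", "IncompatibilityReport", "build_mj_network", "four_gamete_scan"]


# ---------------------------------------------------------------------------
# character coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Character:
    """One mutational character: a substitution column or an indel event."""

    kind: str            # "substitution" | "indel"
    columns: tuple[int, ...]  # 0-based alignment columns spanned
    weight: float

    def label(self, anchors: list[int] | None) -> str:
        cols = self.columns
        if anchors is not None:
            pos = [str(anchors[c]) for c in cols]
        else:
            pos = [str(c + 1) for c in cols]
        if self.kind == "indel":
            return f"indel:{pos[0]}" if len(pos) == 1 else f"indel:{pos[0]}-{pos[-1]}"
        return pos[0]


def _encode_characters(
    alignment: HaplotypeAlignment, indel_weight: float
) -> tuple[list[_Character], dict[str, tuple[str, ...]]]:
    """Condense the alignment into weighted characters and per-id state tuples.

    Substitution columns become one character each (weight 1); each maximal
    run of indel-classed columns becomes a single character (default weight
    2) whose state is the gap pattern across the run.  Missing columns are
    dropped.
    """
    chars: list[_Character] = []
    classes = alignment.site_classes
    i = 0
    while i < alignment.length:
        cls = classes[i]
        if cls == INDEL:
            j = i
            while j + 1 < alignment.length and classes[j + 1] == INDEL:
                j += 1
            chars.append(_Character("indel", tuple(range(i, j + 1)), indel_weight))
            i = j + 1
        else:
            if cls == SUBSTITUTION:
                chars.append(_Character("substitution", (i,), 1.0))
            i += 1
    states = {
        r.id: tuple("".join(r.sequence[c] for c in ch.columns) for ch in chars)
        for r in alignment.records
    }
    return chars, states


def _distance(a: tuple[str, ...], b: tuple[str, ...], weights: list[float]) -> float:
    return sum(w for x, y, w in zip(a, b, weights) if x != y)


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------

@dataclass
class MJNetwork:
    """Haplotype network: observed nodes, median vectors, labelled edges.

    ``graph`` is an undirected :class:`networkx.Graph`; node attributes carry
    ``kind`` ("observed"/"median"), ``multiplicity`` (chromosomes collapsed
    into the node), ``members`` (their ids) and optionally ``populations``.
    Edge attributes carry ``weight`` (summed event weights) and ``positions``
    (labels of the mutated characters).
    """

    graph: nx.Graph
    observed: list[str]
    medians: list[str]
    outgroup: str | None = None

    @property
    def total_weight(self) -> float:
        """Total weight of a minimum spanning tree of the network."""
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return sum(d["weight"] for _, _, d in mst.edges(data=True))


def _msn_links(
    nodes: list[str],
    states: dict[str, tuple[str, ...]],
    weights: list[float],
    epsilon: float,
) -> list[tuple[str, str, float]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge is feasible iff its weight is within epsilon of the minimax path
    weight between its endpoints (the cost of the widest link on the best
    spanning path); with epsilon = 0 this is the classical MSN.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    edges = sorted(
        (( _distance(states[u], states[v], weights), u, v) for u, v in combinations(nodes, 2)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    for d, u, v in edges:
        g.add_edge(u, v, weight=d)
    if len(nodes) == 1:
        return []
    mst = nx.minimum_spanning_tree(g, weight="weight")
    links = []
    for d, u, v in edges:
        path = nx.shortest_path(mst, u, v)
        minimax = max(mst[a][b]["weight"] for a, b in zip(path, path[1:]))
        if d <= minimax + epsilon:
            links.append((u, v, d))
    return links


def _median_state(
    triple: list[str], states: dict[str, tuple[str, ...]]
) -> tuple[str, ...]:
    """Per-character majority consensus; three-way ties keep the first node's
    state (nodes are taken in sorted label order, so the choice is stable)."""
    a, b, c = (states[t] for t in sorted(triple))
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)  # x==y, x==z, or all distinct -> first node's state
    return tuple(out)


def build_mj_network(
    alignment: HaplotypeAlignment,
    epsilon: float = 0,
    indel_weight: float = 2.0,
    pop_map: PopulationMap | None = None,
    outgroup: str | None = None,
    max_iterations: int = 50,
) -> MJNetwork:
    """Build a median-joining network from aligned haplotypes.

    Identical sequences are collapsed into one observed node (labelled by
    the lexicographically first member id).  Median vectors are labelled
    ``mv1``, ``mv2``, ... in insertion order; ties are broken
    lexicographically so the result is deterministic.  ``outgroup`` is
    metadata only: the network stays undirected and the named node (if
    present) is marked as root-adjacent.
    """
    chars, states_by_id = _encode_characters(alignment, indel_weight)
    weights = [c.weight for c in chars]
    # collapse identical haplotypes
    members: dict[tuple[str, ...], list[str]] = {}
    for rid in alignment.ids:
        members.setdefault(states_by_id[rid], []).append(rid)
    node_of: dict[tuple[str, ...], str] = {}
    states: dict[str, tuple[str, ...]] = {}
    observed = []
    for state, ids in members.items():
        name = sorted(ids)[0]
        node_of[state] = name
        states[name] = state
        observed.append(name)
    observed.sort()
    if len(observed) == 1:
        warnings.warn("single distinct haplotype: trivial one-node network")
    nodes = list(observed)
    medians: list[str] = []
    mv_counter = 0
    for _ in range(max_iterations):
        links = _msn_links(nodes, states, weights, epsilon)
        adjacency: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v, _ in links:
            adjacency[u].add(v)
            adjacency[v].add(u)
        # candidate medians from triples u - x - v (x linked to both)
        candidates: dict[tuple[str, ...], float] = {}
        for x in sorted(nodes):
            for u, v in combinations(sorted(adjacency[x]), 2):
                m = _median_state([u, v, x], states)
                if m in states.values() or m in candidates:
                    if m in candidates:
                        cost = sum(
                            _distance(m, states[t], weights) for t in (u, v, x)
                        )
                        candidates[m] = min(candidates[m], cost)
                    continue
                cost = sum(_distance(m, states[t], weights) for t in (u, v, x))
                candidates[m] = cost
        fresh = {m: c for m, c in candidates.items() if m not in node_of}
        if not fresh:
            break
        lam = min(fresh.values())
        added = False
        for m in sorted(fresh, key=lambda s: (fresh[s], s)):
            if fresh[m] <= lam + epsilon:
                mv_counter += 1
                name = f"mv{mv_counter}"
                states[name] = m
                node_of[m] = name
                nodes.append(name)
                medians.append(name)
                added = True
        if not added:
            break
    # prune median vectors whose removal leaves the spanning cost unchanged
    def _mst_weight(node_subset: list[str]) -> float:
        links = _msn_links(node_subset, states, weights, 0)
        g = nx.Graph()
        g.add_nodes_from(node_subset)
        for u, v, d in links:
            g.add_edge(u, v, weight=d)
        mst = nx.minimum_spanning_tree(g, weight="weight")
        return sum(d["weight"] for _, _, d in mst.edges(data=True))

    changed = True
    while changed and medians:
        changed = False
        base = _mst_weight(nodes)
        for m in sorted(medians):
            remaining = [n for n in nodes if n != m]
            if _mst_weight(remaining) <= base + 1e-9:
                nodes = remaining
                medians.remove(m)
                changed = True
                break
    # final graph from the relaxed MSN over surviving nodes
    graph = nx.Graph()
    pop_of = None
    if pop_map is not None:
        pop_of = {c: p for c, p in pop_map.assignments}
    for n in nodes:
        kind = "median" if n in medians else "observed"
        ids = members.get(states[n], []) if kind == "observed" else []
        attrs: dict[str, object] = {
            "kind": kind,
            "multiplicity": len(ids),
            "members": sorted(ids),
        }
        if pop_of is not None and ids:
            pops = sorted({pop_of[i] for i in ids if i in pop_of})
            attrs["populations"] = pops
        graph.add_node(n, **attrs)
    for u, v, d in _msn_links(nodes, states, weights, epsilon):
        diff = [
            chars[k].label(alignment.anchors)
            for k in range(len(chars))
            if states[u][k] != states[v][k]
        ]
        graph.add_edge(u, v, weight=d, positions=diff)
    if outgroup is not None and outgroup in graph:
        graph.nodes[outgroup]["root_adjacent"] = True
    return MJNetwork(graph, observed, medians, outgroup)


# ---------------------------------------------------------------------------
# four-gamete scan
# ---------------------------------------------------------------------------

@dataclass
class IncompatibilityReport:
    """Four-gamete violations and the inferred recombination interval.

    ``pairs`` lists incompatible site pairs as 1-based alignment columns
    (or genomic anchors when the alignment carries them).  For a single
    crossover every incompatible pair spans the breakpoint, so the interval
    is bounded by the innermost incompatible pair; if no single interval
    explains all pairs, ``single_breakpoint`` is False and the interval
    falls back to the narrowest incompatible pair.
    """

    pairs: list[tuple[int, int]]
    breakpoint_interval: tuple[int, int] | None = None
    single_breakpoint: bool = True
    columns: list[int] = field(default_factory=list)  # biallelic columns scanned


def four_gamete_scan(
    alignment: HaplotypeAlignment, chromosomes: list[str] | None = None
) -> IncompatibilityReport:
    """Scan all biallelic substitution-site pairs for four-gamete violations."""
    sub = alignment if chromosomes is None else alignment.subset(chromosomes)
    cols = []
    for i, cls in enumerate(sub.site_classes):
        if cls != SUBSTITUTION:
            continue
        alleles = {r.sequence[i] for r in sub.records}
        if len(alleles) == 2:
            cols.append(i)
    anchors = sub.anchors

    def _label(c: int) -> int:
        return anchors[c] if anchors is not None else c + 1

    pairs: list[tuple[int, int]] = []
    raw_pairs: list[tuple[int, int]] = []
    for a, b in combinations(cols, 2):
        gametes = {(r.sequence[a], r.sequence[b]) for r in sub.records}
        if len(gametes) == 4:
            raw_pairs.append((a, b))
            pairs.append((_label(a), _label(b)))
    if not raw_pairs:
        return IncompatibilityReport(pairs=[], breakpoint_interval=None, columns=[_label(c) for c in cols])
    left = max(a for a, _ in raw_pairs)
    right = min(b for _, b in raw_pairs)
    if left < right:
        interval = (_label(left), _label(right))
        single = True
    else:
        a, b = min(raw_pairs, key=lambda p: (p[1] - p[0], p[0]))
        interval = (_label(a), _label(b))
        single = False
    return IncompatibilityReport(
        pairs=pairs,
        breakpoint_interval=interval,
        single_breakpoint=single,
        columns=[_label(c) for c in cols],
    )
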