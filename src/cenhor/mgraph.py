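"""Monomer adjacency graph and shifted monomer-sets.

The directed *monomer-graph* of a monostring has one vertex per monomer and
an edge (M, M') of weight w when M' immediately follows M at w positions;
pairs separated by the non-monomeric token contribute nothing.

A tandem repeat unit is only defined up to a cyclic shift, and in a nested
tandem repeat shifting the monomer start positions does not merely rotate
each monomer: the unit crossing a block boundary becomes a *hybrid* of the
two adjacent monomers.  ``shift_monomers`` therefore derives the i-shifted
monomer-set from the monomer-graph: every edge (M, M') yields a candidate
formed by the i-suffix of M followed by the (|M'|-i)-prefix of M', and
near-identical candidates (divergence <= threshold) are merged by
single-linkage, the merged representative being the candidate consensus
weighted by source-edge multiplicity.  Different published monomer sets for
the same array typically differ only by such a shift (94 nt for the human
reference set), so this is the bridge for comparing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .align import consensus
from .blocks import MonoString, NON_MONOMERIC_TOKEN, _single_linkage

__all__ = [
    "build_monomer_graph",
    "shift_monomers",
    "build_shifted_monomer_graph",
    "ShiftedMonomer",
]


@dataclass(frozen=True)
class ShiftedMonomer:
    """A shifted monomer with provenance: the source edges it merges."""

    id: str
    sequence: str
    sources: tuple[tuple[str, str], ...]  # (M, M') edges, by weight desc
    weight: int  # total source-edge weight


def build_monomer_graph(monostring: MonoString) -> nx.DiGraph:
    """Directed graph of consecutive monomer pairs with multiplicities."""
    g = nx.DiGraph()
    for sym in monostring.symbols:
        if sym != NON_MONOMERIC_TOKEN:
            g.add_node(sym)
    for a, b in zip(monostring.symbols, monostring.symbols[1:]):
        if NON_MONOMERIC_TOKEN in (a, b):
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def _shift_candidate(m: str, m2: str, i: int) -> str:
    """i-suffix of m followed by the (|m2|-i)-prefix of m2."""
    return m[len(m) - i :] + m2[: len(m2) - i]


def shift_monomers(
    monostring: MonoString,
    monomers: dict[str, str],
    i: int,
    merge_threshold: float,
) -> list[ShiftedMonomer]:
    """Derive the i-shifted monomer-set from the monomer-graph.

    One candidate per monomer-graph edge; candidates are merged by
    single-linkage under ``divergence <= merge_threshold`` and each merged
    set is represented by its consensus weighted by source-edge weight.
    Output ids are "X-Y" labels from the heaviest source edge.
    """
    if not monomers:
        raise ValueError("monomer set must be non-empty")
    if not 0 < i < min(len(s) for s in monomers.values()):
        raise ValueError("shift must satisfy 0 < i < min monomer length")
    graph = build_monomer_graph(monostring)
    edges = sorted(graph.edges(data="weight"))
    cands = [
        (_shift_candidate(monomers[a], monomers[b], i), (a, b), w)
        for a, b, w in edges
    ]
    clusters = _single_linkage([c[0] for c in cands], merge_threshold)
    out: list[ShiftedMonomer] = []
    for members in clusters:
        seqs = [cands[k][0] for k in members]
        weights = [cands[k][2] for k in members]
        sources = sorted(
            ((cands[k][1], cands[k][2]) for k in members),
            key=lambda t: (-t[1], t[0]),
        )
        rep = consensus(seqs, weights=weights).consensus
        label = "-".join(sources[0][0])
        out.append(
            ShiftedMonomer(
                id=label,
                sequence=rep,
                sources=tuple(s for s, _ in sources),
                weight=sum(weights),
            )
        )
    return out


def build_shifted_monomer_graph(
    monostring: MonoString,
    monomers: dict[str, str],
    shifted: list[ShiftedMonomer],
) -> nx.DiGraph:
    """Graph on shifted monomers from consecutive monomer triples.

    Each triple (M, M', M'') in the monostring contributes one unit of
    weight to the edge between the shifted monomers covering (M, M') and
    (M', M''), mapped through the merging recorded in ``shifted``.
    Triples interrupted by the non-monomeric token are skipped.
    """
    edge_to_shift: dict[tuple[str, str], str] = {}
    for sm in shifted:
        for src in sm.sources:
            edge_to_shift[src] = sm.id
    g = nx.DiGraph()
    g.add_nodes_from(sm.id for sm in shifted)
    syms = monostring.symbols
    for a, b, c in zip(syms, syms[1:], syms[2:]):
        if NON_MONOMERIC_TOKEN in (a, b, c):
            continue
        u = edge_to_shift.get((a, b))
        v = edge_to_shift.get((b, c))
        if u is None or v is None:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g
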