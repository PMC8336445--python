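"""Monomer inference: the iterative monomer-set generator.

Starting from a single initial consensus monomer (for human alpha satellite,
the ~171 bp consensus), the generator alternates between

1. decomposing the array into blocks against the current monomer set,
2. building the *block-graph* on unresolved blocks (edges connect blocks
   whose divergence is below maxResolvedDivergence/2),
3. adding the consensus of the largest connected component as a new
   monomer, dropping monomers that are no block's best match, and
   recomputing every monomer as the consensus of its resolved blocks,

until the monomer set *resolves* the array: the fraction of resolved blocks
exceeds FractionResolvedBlocks and every remaining block is non-monomeric.
On the final set each monomer is a fixed point — it equals the consensus of
the blocks it resolves.

The module also computes per-monomer statistics (count, radius, separation,
separation ratio, frequency class) and detects *hybrid monomers*: infrequent
monomers that match, within MaxHybridDivergence, the concatenation of an
i-prefix of one frequent monomer with a j-suffix of another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .align import consensus, divergence, edit_distance
from .blocks import Block, DecompositionParams, decompose

__all__ = [
    "Monomer",
    "MonomerGenParams",
    "HybridAnnotation",
    "ConvergenceError",
    "build_block_graph",
    "generate_monomers",
    "monomer_stats",
    "detect_hybrids",
    "resolves",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HybridAnnotation:
    """M matches prefix_x(i) + suffix_y(j) at the given divergence."""

    x: str
    i: int
    y: str
    j: int
    divergence: float

    def __str__(self) -> str:
        return f"{self.x}({self.i})+{self.y}({self.j})"


@dataclass
class Monomer:
    """A named consensus monomer with its statistics.

    radius is the maximum edit distance between the consensus and its
    blocks; separation the minimum consensus-to-consensus edit distance to
    any other monomer; separation_ratio their quotient (infinity when the
    radius is 0, absent when there is no other monomer).
    """

    id: str
    sequence: str
    count: int = 0
    freq_class: str | None = None  # frequent | infrequent | rare
    radius: int | None = None
    separation: int | None = None
    separation_ratio: float | None = None
    hybrid: HybridAnnotation | None = None
    length_uniform: bool | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MonomerGenParams:
    """Parameters of the monomer generator (defaults are the human ones)."""

    max_resolved_divergence: float = 0.05
    max_divergence: float = 0.40
    fraction_resolved_blocks: float = 0.95
    freq_ceiling: int = 40
    rare_monomer_count: int = 5
    max_hybrid_divergence: float = 0.01
    length: int = 171
    max_length_divergence: float | None = None  # default 0.01 * length
    max_iterations: int = 100

    @property
    def length_tolerance(self) -> float:
        if self.max_length_divergence is not None:
            return self.max_length_divergence
        return 0.01 * self.length

    def decomposition(self) -> DecompositionParams:
        return DecompositionParams(
            self.max_resolved_divergence, self.max_divergence
        )


class ConvergenceError(RuntimeError):
    """Raised when the generator fails to resolve the array.

    Carries the per-iteration log table in ``iteration_log``.
    """

    def __init__(self, message: str, iteration_log: list[dict]):
        super().__init__(message)
        self.iteration_log = iteration_log


# ---------------------------------------------------------------------------
# block-graph


def build_block_graph(
    seqs: Sequence[str],
    threshold: float,
    method: str = "sketch",
    kmer: int = 7,
) -> nx.Graph:
    """Graph on block indices; edge iff divergence(u, v) < threshold.

    ``method="sketch"`` prunes candidate pairs with a k-mer filter before
    exact verification; ``method="bruteforce"`` verifies every pair.  Both
    produce the identical graph: the filter relies on the fact that a pair
    at edit distance e shares all k-mer types outside the <= e edited
    regions, hence at least (n_types - e*k) types, which is a necessary
    condition for divergence < threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    if method == "bruteforce":
        pairs = (
            (u, v)
            for u in range(len(seqs))
            for v in range(u + 1, len(seqs))
        )
    elif method == "sketch":
        pairs = _sketch_candidates(seqs, threshold, kmer)
    else:
        raise ValueError(f"unknown method {method!r}")
    for u, v in pairs:
        if divergence(seqs[u], seqs[v]) < threshold:
            g.add_edge(u, v)
    return g


def _kmer_set(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def _sketch_candidates(seqs: Sequence[str], threshold: float, k: int):
    """Candidate pairs surviving the shared-k-mer-type lower bound."""
    ksets = [_kmer_set(s, k) for s in seqs]
    index: dict[str, list[int]] = {}
    order = sorted(range(len(seqs)), key=lambda i: len(seqs[i]))
    shared: dict[tuple[int, int], int] = {}
    for i in order:
        for km in ksets[i]:
            for j in index.get(km, ()):
                key = (j, i) if j < i else (i, j)
                shared[key] = shared.get(key, 0) + 1
            index.setdefault(km, []).append(i)
    for (u, v), common in shared.items():
        lu, lv = len(seqs[u]), len(seqs[v])
        emax = int(math.ceil(threshold * max(lu, lv)))
        if max(lu, lv) - min(lu, lv) > emax:
            continue
        need = max(len(ksets[u]), len(ksets[v])) - emax * k
        if common >= need:
            yield u, v


# ---------------------------------------------------------------------------
# generator loop


def resolves(blocks: Sequence[Block], fraction_resolved: float) -> bool:
    """True if the resolved fraction exceeds the threshold and every
    remaining block is non-monomeric."""
    n = len(blocks)
    if n == 0:
        return False
    n_res = sum(b.status == "resolved" for b in blocks)
    n_unres = sum(b.status == "unresolved" for b in blocks)
    return n_res / n > fraction_resolved and n_unres == 0


def _largest_component(graph: nx.Graph, blocks: Sequence[Block]) -> list[int]:
    """Largest component; ties broken by smallest minimum block start."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(blocks[i].start for i in c)),
    )
    return comps[0]


def generate_monomers(
    sequence: str,
    initial_monomer: str,
    params: MonomerGenParams | None = None,
    seq_id: str = "seq",
    graph_method: str = "sketch",
) -> tuple[dict[str, str], list[Block], list[dict]]:
    """Grow a monomer set from a single initial monomer until it resolves
    the array.

    Returns (monomer id -> sequence, final block list, iteration log).  The
    iteration log has one row per iteration with the resolved / unresolved /
    non-monomeric block counts, the largest block-graph component size and
    the radius, separation (to previously generated monomers) and length of
    the newly added monomer.
    """
    if params is None:
        params = MonomerGenParams()
    if abs(len(initial_monomer) - params.length) > params.length_tolerance:
        raise ValueError(
            "initial monomer length outside Length +- MaxLengthDivergence"
        )
    dparams = params.decomposition()
    monomers: dict[str, str] = {"m1": initial_monomer.upper()}
    next_id = 2
    log: list[dict] = []

    for it in range(params.max_iterations):
        blocks = decompose(sequence, monomers, dparams, seq_id=seq_id)
        n_res = sum(b.status == "resolved" for b in blocks)
        n_unres = sum(b.status == "unresolved" for b in blocks)
        n_nm = len(blocks) - n_res - n_unres
        row = {
            "iteration": it,
            "resolved": n_res,
            "unresolved": n_unres,
            "non_monomeric": n_nm,
            "largest_component": None,
            "radius": None,
            "separation": None,
            "monomer_length": None,
        }
        if resolves(blocks, params.fraction_resolved_blocks):
            log.append(row)
            logger.info("iteration %d: resolved, %d monomers", it, len(monomers))
            used = {b.best_monomer for b in blocks}
            monomers = {m: s for m, s in monomers.items() if m in used}
            monomers = _final_consensi(blocks, sequence, monomers)
            blocks = decompose(sequence, monomers, dparams, seq_id=seq_id)
            return monomers, blocks, log

        unres = [b for b in blocks if b.status == "unresolved"]
        if not unres:
            log.append(row)
            raise ConvergenceError(
                "no unresolved blocks left to cluster, but the resolved "
                "fraction is below FractionResolvedBlocks",
                log,
            )
        graph = build_block_graph(
            [b.sequence(sequence) for b in unres],
            params.max_resolved_divergence / 2,
            method=graph_method,
        )
        comp = _largest_component(graph, unres)
        comp_seqs = [unres[i].sequence(sequence) for i in comp]
        new_seq = consensus(comp_seqs).consensus

        # drop monomers that are no block's best match
        used = {b.best_monomer for b in blocks}
        monomers = {m: s for m, s in monomers.items() if m in used}
        # recompute each monomer as the consensus of its resolved blocks
        monomers = _final_consensi(blocks, sequence, monomers)

        row["largest_component"] = len(comp)
        row["radius"] = max(edit_distance(new_seq, s) for s in comp_seqs)
        if monomers:
            row["separation"] = min(
                edit_distance(new_seq, s) for s in monomers.values()
            )
        row["monomer_length"] = len(new_seq)
        log.append(row)
        logger.info(
            "iteration %d: resolved=%d unresolved=%d non_monomeric=%d "
            "|largest comp|=%d radius=%s sep=%s len=%s",
            it, n_res, n_unres, n_nm, len(comp),
            row["radius"], row["separation"], row["monomer_length"],
        )

        monomers[f"m{next_id}"] = new_seq
        next_id += 1

    raise ConvergenceError(
        f"monomer generation did not resolve the array within "
        f"{params.max_iterations} iterations",
        log,
    )


def _final_consensi(
    blocks: Sequence[Block], sequence: str, monomers: Mapping[str, str]
) -> dict[str, str]:
    """Replace each monomer by the consensus of its resolved blocks."""
    out: dict[str, str] = {}
    for m, seq in monomers.items():
        mine = [
            b.sequence(sequence)
            for b in blocks
            if b.best_monomer == m and b.status == "resolved"
        ]
        out[m] = consensus(mine).consensus if mine else seq
    return out


# ---------------------------------------------------------------------------
# statistics


def monomer_stats(
    monomers: Mapping[str, str],
    blocks: Sequence[Block],
    sequence: str,
    params: MonomerGenParams | None = None,
) -> dict[str, Monomer]:
    """Fill count, radius, separation, separation ratio and frequency class.

    Counts and radii are taken over each monomer's blocks (excluding
    non-monomeric blocks, which belong to no monomer); the frequency
    threshold uses the total number of blocks.
    """
    if params is None:
        params = MonomerGenParams()
    total = len(blocks)
    out: dict[str, Monomer] = {}
    for mid in sorted(monomers):
        seq = monomers[mid]
        mine = [
            b for b in blocks
            if b.best_monomer == mid and b.status != "non_monomeric"
        ]
        count = len(mine)
        radius = (
            max(edit_distance(seq, b.sequence(sequence)) for b in mine)
            if mine
            else None
        )
        others = [monomers[o] for o in monomers if o != mid]
        separation = (
            min(edit_distance(seq, o) for o in others) if others else None
        )
        if separation is None or radius is None:
            ratio = None
        elif radius == 0:
            ratio = math.inf
        else:
            ratio = separation / radius
        if count > total / params.freq_ceiling:
            freq = "frequent"
        elif count <= params.rare_monomer_count:
            freq = "rare"
        else:
            freq = "infrequent"
        out[mid] = Monomer(
            id=mid,
            sequence=seq,
            count=count,
            freq_class=freq,
            radius=radius,
            separation=separation,
            separation_ratio=ratio,
            length_uniform=abs(len(seq) - params.length)
            <= params.length_tolerance,
        )
    return out


# ---------------------------------------------------------------------------
# hybrid monomers


def _prefix_table(a: str, b: str) -> np.ndarray:
    """f[i, t] = edit distance between a[:i] and b[:t] (full DP table)."""
    la, lb = len(a), len(b)
    f = np.empty((la + 1, lb + 1), dtype=np.int32)
    f[0] = np.arange(lb + 1)
    t = np.arange(lb + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, la + 1):
        cost = (bb != ord(a[i - 1])).astype(np.int32)
        cand = np.minimum(f[i - 1] + 1, np.concatenate(([i], f[i - 1, :-1] + cost)))
        cand[0] = i
        # resolve left-to-right insertion chain: f[i,t] = min_s cand[s]+(t-s)
        f[i] = np.minimum.accumulate(cand - t) + t
    return f


def detect_hybrids(
    candidates: Mapping[str, str],
    parents: Mapping[str, str],
    max_hybrid_divergence: float = 0.01,
) -> dict[str, HybridAnnotation]:
    """Annotate candidates matching a frequent-monomer prefix+suffix join.

    For every candidate M and every ordered pair of distinct parents
    (X, Y), the divergence between M and X[:i] + Y[-j:] is minimised over
    cut points 1 <= i <= |X|, 1 <= j <= |Y| using forward/backward
    edit-distance tables (min over the split point of M).  Since the edit
    distance is at least the length difference, only cut points with
    i + j within a divergence-derived band around |M| can pass the
    threshold; the search over that band is exact.  M is annotated with the
    best X(i)+Y(j) iff its divergence does not exceed
    ``max_hybrid_divergence``.
    """
    if not parents:
        raise ValueError("parent (frequent) monomer set must be non-empty")
    result: dict[str, HybridAnnotation] = {}
    pids = sorted(parents)
    for cid in sorted(candidates):
        m = candidates[cid]
        lm = len(m)
        # admissible total length band: a concatenate of length s has
        # divergence >= |s - lm| / max(s, lm), so outside the band the
        # threshold cannot be met.
        s_lo = math.floor(lm * (1 - max_hybrid_divergence))
        s_hi = math.ceil(lm / (1 - max_hybrid_divergence)) if \
            max_hybrid_divergence < 1 else lm * 2
        best: tuple | None = None
        for xid in pids:
            for yid in pids:
                if xid == yid:
                    continue
                x, y = parents[xid], parents[yid]
                f = _prefix_table(x, m)  # f[i, t] = d(x[:i], m[:t])
                g = _prefix_table(y[::-1], m[::-1])
                gg = g[:, ::-1]  # gg[j, t] = d(y[-j:], m[t:])
                for i in range(1, len(x) + 1):
                    j_lo = max(1, s_lo - i)
                    j_hi = min(len(y), s_hi - i)
                    if j_lo > j_hi:
                        continue
                    dist = (f[i][None, :] + gg[j_lo : j_hi + 1, :]).min(axis=1)
                    j = np.arange(j_lo, j_hi + 1)
                    div = dist / np.maximum(lm, i + j)
                    jbest = int(np.argmin(div))
                    cand = (
                        float(div[jbest]), xid, yid, i, int(j[jbest]),
                    )
                    if best is None or cand < best:
                        best = cand
        if best is not None and best[0] <= max_hybrid_divergence:
            dv, xid, yid, i, j = best
            result[cid] = HybridAnnotation(xid, i, yid, j, dv)
    return result
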