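"""Partitioning a satellite array into monomeric blocks.

A satellite array is annotated by tiling it with consecutive *blocks*, each
globally aligned to its most similar monomer.  The tiling is found by a
dynamic program over sequence positions: at every position the best-scoring
chain of blocks ending there is extended by aligning every candidate monomer
against a suffix of the already-tiled prefix (match +1, mismatch/indel -1,
block boundaries free).  The per-block divergences div1 (to the best
monomer) and div2 (to the runner-up) then classify the block:

* resolved        div1 <  maxResolvedDivergence   (default 5%)
* non-monomeric   div1 >  maxDivergence           (default 40%)
* unresolved      otherwise

The classified tiling is rewritten as a *monostring* over the monomer
alphabet plus a ``?`` token for non-monomeric blocks — the representation
that all higher-order repeat inference operates on.

``augment_with_nonmonomeric`` extends the alphabet with consensi of
clustered non-monomeric runs (e.g. LINE/Alu insertions) and re-decomposes,
so that transposon insertions are reported as single well-matched blocks
instead of runs of poorly matched monomer blocks.

The inner DP runs under numba over byte arrays; a brute-force tiling
enumeration with the same scoring is kept in the test-suite as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .align import consensus, divergence

__all__ = [
    "Block",
    "DecompositionParams",
    "MonoString",
    "NON_MONOMERIC_TOKEN",
    "decompose",
    "classify_block",
    "to_monostring",
    "augment_with_nonmonomeric",
    "reverse_complement",
]

#: Symbol standing for a non-monomeric block in a monostring.
NON_MONOMERIC_TOKEN = "?"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DecompositionParams:
    """Thresholds governing block classification.

    maxResolvedDivergence and maxDivergence are the two divergence cutoffs
    separating resolved / unresolved / non-monomeric blocks; allow_reverse
    additionally offers every monomer's reverse complement as a candidate.
    """

    max_resolved_divergence: float = 0.05
    max_divergence: float = 0.40
    allow_reverse: bool = False

    def __post_init__(self):
        if not 0 < self.max_resolved_divergence < self.max_divergence <= 1:
            raise ValueError(
                "require 0 < max_resolved_divergence < max_divergence <= 1"
            )


@dataclass(frozen=True)
class Block:
    """One tile of the array: a half-open interval matched to a monomer."""

    seq_id: str
    start: int
    end: int
    best_monomer: str
    second_monomer: str | None
    div1: float
    div2: float | None
    status: str  # resolved | unresolved | non_monomeric
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, seq: str) -> str:
        return seq[self.start : self.end]


@dataclass
class MonoString:
    """The array rewritten over the monomer alphabet.

    ``symbols[k]`` is the monomer id of block ``blocks[k]`` (or the ``?``
    token for a non-monomeric block), so the positional back-map from
    symbols to genomic intervals is the index itself.
    """

    seq_id: str
    symbols: list[str]
    blocks: list[Block] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


def classify_block(div1: float, params: DecompositionParams) -> str:
    """Status of a block as a pure function of div1 and the thresholds."""
    if div1 < params.max_resolved_divergence:
        return "resolved"
    if div1 > params.max_divergence:
        return "non_monomeric"
    return "unresolved"


@njit(cache=False)
def _tile_dp(seq, cat, starts):  # pragma: no cover - exercised via decompose
    """Best tiling of ``seq`` by blocks aligned to monomers.

    seq: uint8 array of the sequence; cat: concatenated monomer bytes;
    starts: offsets of each monomer in cat (len M+1).  Scoring: match +1,
    mismatch/indel -1, block boundaries free.  Returns (D, bstart, bmon)
    where D[i] is the optimal score of a tiling of seq[:i], and
    bstart[i]/bmon[i] describe the last block of that tiling.
    """
    n = seq.size
    m = starts.size - 1
    neg = -(10 ** 9)

    off = np.empty(m + 1, np.int64)
    for k in range(m + 1):
        off[k] = starts[k] + k
    ncell = cat.size + m

    col = np.full(ncell, neg, np.int64)
    cst = np.zeros(ncell, np.int64)
    newcol = np.full(ncell, neg, np.int64)
    newst = np.zeros(ncell, np.int64)

    d = np.empty(n + 1, np.int64)
    bstart = np.empty(n + 1, np.int64)
    bmon = np.empty(n + 1, np.int64)
    d[0] = 0
    bstart[0] = 0
    bmon[0] = -1

    # column at i=0: block may start here; leading monomer-char deletions
    # allow a first block matching a monomer suffix.
    for k in range(m):
        o = off[k]
        lk = starts[k + 1] - starts[k]
        col[o] = 0
        cst[o] = 0
        for j in range(1, lk + 1):
            col[o + j] = col[o + j - 1] - 1
            cst[o + j] = 0

    for i in range(1, n + 1):
        c = seq[i - 1]
        best = neg
        bm = -1
        bs = 0
        for k in range(m):
            o = off[k]
            lk = starts[k + 1] - starts[k]
            base = starts[k]
            for j in range(1, lk + 1):
                sc = 1 if cat[base + j - 1] == c else -1
                v = col[o + j - 1] + sc  # diagonal
                s = cst[o + j - 1]
                v2 = col[o + j] - 1  # sequence char inserted
                if v2 > v:
                    v = v2
                    s = cst[o + j]
                if j >= 2:
                    v3 = newcol[o + j - 1] - 1  # monomer char deleted
                    if v3 > v:
                        v = v3
                        s = newst[o + j - 1]
                newcol[o + j] = v
                newst[o + j] = s
            if newcol[o + lk] > best:
                best = newcol[o + lk]
                bm = k
                bs = newst[o + lk]
        d[i] = best
        bmon[i] = bm
        bstart[i] = bs
        # row 0: open a fresh block at i, or extend an open block by a
        # leading sequence insertion; then sweep leading monomer deletions
        for k in range(m):
            o = off[k]
            lk = starts[k + 1] - starts[k]
            if col[o] - 1 > best:
                newcol[o] = col[o] - 1
                newst[o] = cst[o]
            else:
                newcol[o] = best
                newst[o] = i
            for j in range(1, lk + 1):
                if newcol[o + j - 1] - 1 > newcol[o + j]:
                    newcol[o + j] = newcol[o + j - 1] - 1
                    newst[o + j] = newst[o + j - 1]
        tmp = col
        col = newcol
        newcol = tmp
        tmp = cst
        cst = newst
        newst = tmp
    return d, bstart, bmon


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def _boundaries(seq: str, candidates: Sequence[str]) -> list[tuple[int, int, int]]:
    """Run the tiling DP; return (start, end, candidate_index) blocks."""
    cat = np.concatenate([_encode(c) for c in candidates])
    starts = np.zeros(len(candidates) + 1, np.int64)
    for k, c in enumerate(candidates):
        starts[k + 1] = starts[k] + len(c)
    d, bstart, bmon = _tile_dp(_encode(seq), cat, starts)
    out = []
    i = len(seq)
    while i > 0:
        s = int(bstart[i])
        if s >= i:  # safety: should not happen, blocks are non-empty
            s = i - 1
        out.append((s, i, int(bmon[i])))
        i = s
    out.reverse()
    return out


def decompose(
    sequence: str,
    monomers: Mapping[str, str],
    params: DecompositionParams | None = None,
    seq_id: str = "seq",
    _nonmonomeric_ids: frozenset[str] = frozenset(),
) -> list[Block]:
    """Tile ``sequence`` with blocks, each matched to its best monomer.

    ``monomers`` maps monomer id -> nucleotide sequence.  The DP chooses the
    block boundaries; for each block, div1/div2 and the best/second monomer
    are then recomputed by global alignment against every monomer (ties
    broken by lexicographic monomer id).  Ids listed in ``_nonmonomeric_ids``
    mark alphabet entries that represent non-monomeric strings: blocks whose
    best match is such an entry are classified non_monomeric regardless of
    divergence.
    """
    if params is None:
        params = DecompositionParams()
    if not sequence:
        raise ValueError("cannot decompose an empty sequence")
    if not monomers:
        raise ValueError("monomer set must be non-empty")

    ids = sorted(monomers)  # fixed order -> deterministic DP tie-breaking
    cand_ids: list[str] = list(ids)
    cand_seqs: list[str] = [monomers[i] for i in ids]
    strands = ["+"] * len(ids)
    if params.allow_reverse:
        for i in ids:
            cand_ids.append(i)
            cand_seqs.append(reverse_complement(monomers[i]))
            strands.append("-")

    tiles = _boundaries(sequence.upper(), cand_seqs)

    blocks: list[Block] = []
    for s, e, k in tiles:
        sub = sequence[s:e].upper()
        scored: list[tuple[float, str, str]] = []
        for cid, cseq, strand in zip(cand_ids, cand_seqs, strands):
            scored.append((divergence(sub, cseq), cid, strand))
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        div1, best, strand = scored[0]
        second = div2 = None
        for dv, cid, _ in scored[1:]:
            if cid != best:
                second, div2 = cid, dv
                break
        status = (
            "non_monomeric"
            if best in _nonmonomeric_ids
            else classify_block(div1, params)
        )
        blocks.append(
            Block(seq_id, s, e, best, second, div1, div2, status, strand)
        )
    _assert_tiling(blocks, len(sequence))
    return blocks


def _assert_tiling(blocks: Sequence[Block], seq_len: int) -> None:
    pos = 0
    for b in blocks:
        if b.start != pos or b.end <= b.start:
            raise AssertionError("blocks do not tile the sequence")
        pos = b.end
    if pos != seq_len:
        raise AssertionError("blocks do not cover the full sequence")


def to_monostring(
    blocks: Sequence[Block], seq_id: str | None = None
) -> MonoString:
    """Rewrite a block tiling as a string over the monomer alphabet.

    Resolved and unresolved blocks contribute their best monomer id;
    non-monomeric blocks contribute the ``?`` token.
    """
    symbols = [
        NON_MONOMERIC_TOKEN if b.status == "non_monomeric" else b.best_monomer
        for b in blocks
    ]
    sid = seq_id if seq_id is not None else (blocks[0].seq_id if blocks else "seq")
    return MonoString(sid, symbols, list(blocks))


def nonmonomeric_runs(blocks: Sequence[Block]) -> list[tuple[int, int]]:
    """Maximal runs of non-monomeric blocks as (start, end) genomic intervals."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    for b in blocks:
        if b.status == "non_monomeric":
            cur = (b.start, b.end) if cur is None else (cur[0], b.end)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    return runs


def augment_with_nonmonomeric(
    sequence: str,
    monomers: Mapping[str, str],
    params: DecompositionParams | None = None,
    seq_id: str = "seq",
) -> tuple[dict[str, str], list[Block]]:
    """Add non-monomeric region consensi to the alphabet and re-decompose.

    Maximal runs of non-monomeric blocks from a first decomposition are
    extracted, single-linkage clustered at divergence <= maxResolvedDivergence,
    and each cluster consensus is added to the alphabet under an ``nm<k>`` id
    flagged as non-monomeric.  Returns the extended alphabet and the new
    decomposition (identical to the first one when no non-monomeric block
    exists).
    """
    if params is None:
        params = DecompositionParams()
    first = decompose(sequence, monomers, params, seq_id=seq_id)
    runs = nonmonomeric_runs(first)
    if not runs:
        return dict(monomers), first

    segs = [sequence[s:e].upper() for s, e in runs]
    clusters = _single_linkage(segs, params.max_resolved_divergence)
    extended = dict(monomers)
    nm_ids = set()
    for k, members in enumerate(clusters):
        cid = f"nm{k + 1}"
        extended[cid] = consensus([segs[i] for i in members]).consensus
        nm_ids.add(cid)
    blocks = decompose(
        sequence,
        extended,
        params,
        seq_id=seq_id,
        _nonmonomeric_ids=frozenset(nm_ids),
    )
    return extended, blocks


def _single_linkage(strings: Sequence[str], threshold: float) -> list[list[int]]:
    """Single-linkage clusters under divergence <= threshold (indices)."""
    n = len(strings)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if divergence(strings[i], strings[j]) <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sorted(groups.values(), key=lambda g: g[0])]
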