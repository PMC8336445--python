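"""Edit-distance, divergence and consensus primitives.

Every inference stage of the toolkit reduces, at some point, to one of three
questions about nucleotide strings: how far apart are two strings (unit-cost
Levenshtein distance), how far apart relative to their length (divergence,
i.e. edit distance over the length of the longer string), and what is the
consensus of a cluster of similar strings.

The consensus is computed by a deterministic star (center-string) alignment:
a medoid of the inputs is chosen as the center, every input is globally
aligned against it, and a column-wise weighted majority is taken over the
resulting profile.  The contract is only the consensus string itself, so the
engine is pluggable; this one needs no external binary and is reproducible
given the input order.

Ambiguity codes (``N`` etc.) are kept as ordinary symbols and therefore
mismatch every other base, which is the conservative choice for satellite
consensi.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

__all__ = [
    "edit_distance",
    "divergence",
    "consensus",
    "ConsensusResult",
]

#: Fixed nucleotide tie-breaking order used throughout the package.
_BASE_ORDER = {b: i for i, b in enumerate("ACGT")}

# Number of leading strings among which the star-alignment center (medoid)
# is selected; keeps center selection O(k^2) instead of O(n^2).
_MEDOID_POOL = 25


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus string together with the number of supporting inputs."""

    consensus: str
    support: int


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two strings.

    Substitutions, insertions and deletions all cost 1.  Empty strings are
    allowed: ``edit_distance(s, "") == len(s)``.
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def divergence(a: str, b: str) -> float:
    """Edit distance divided by the length of the longer string.

    Symmetric, zero iff the strings are equal, and never exceeds 1.

    Raises
    ------
    ValueError
        If both strings are empty (the ratio is undefined).
    """
    longest = max(len(a), len(b))
    if longest == 0:
        raise ValueError("divergence is undefined for two empty strings")
    return edit_distance(a, b) / longest


def _tie_break_column(counts: Counter) -> str:
    """Majority symbol of one profile column.

    Gaps lose ties to any nucleotide; nucleotide ties resolve A<C<G<T.
    Symbols outside ACGT (ambiguity codes) sort after T, before the gap.
    """
    best = None
    best_key = None
    for sym, n in counts.items():
        rank = (2, 0) if sym == "-" else (0, _BASE_ORDER.get(sym)) \
            if sym in _BASE_ORDER else (1, sym)
        key = (-n, rank)
        if best is None or key < best_key:
            best, best_key = sym, key
    return best


def _tie_break_insert(counts: Counter) -> str:
    """Majority inserted segment between two center columns.

    The empty segment (no insertion) loses ties to any non-empty one;
    non-empty ties resolve to the lexicographically smallest segment.
    """
    best = None
    best_key = None
    for seg, n in counts.items():
        key = (-n, seg == "", seg)
        if best is None or key < best_key:
            best, best_key = seg, key
    return best


def consensus(
    strings: Sequence[str],
    weights: Iterable[float] | None = None,
) -> ConsensusResult:
    """Column-majority consensus of a star alignment of ``strings``.

    The center is the medoid (minimum total edit distance) of the first
    ``min(n, 25)`` inputs; every input is then globally aligned to the
    center with edlib and a per-column weighted majority vote is taken,
    treating each inserted segment between center columns as an atomic
    candidate.  Deterministic given the input order.

    Parameters
    ----------
    strings
        Non-empty ordered collection of nucleotide strings.
    weights
        Optional per-string vote weights (default: 1 each).
    """
    strings = list(strings)
    if not strings:
        raise ValueError("consensus of an empty string list is undefined")
    if weights is None:
        weights = [1.0] * len(strings)
    else:
        weights = list(weights)
        if len(weights) != len(strings):
            raise ValueError("weights must match strings in length")

    if len(set(strings)) == 1:
        return ConsensusResult(strings[0], len(strings))

    pool = strings[:_MEDOID_POOL]
    totals = [
        sum(edit_distance(s, t) for t in pool if t is not s) for s in pool
    ]
    center = pool[totals.index(min(totals))]

    ncol = len(center)
    # Substitution/deletion profile per center column; insertion profile per
    # inter-column gap (ncol + 1 of them, inserts[g] sits before column g).
    columns: list[Counter] = [Counter() for _ in range(ncol)]
    inserts: list[Counter] = [Counter() for _ in range(ncol + 1)]

    for s, w in zip(strings, weights):
        if s == center:
            for j, ch in enumerate(center):
                columns[j][ch] += w
            for g in range(ncol + 1):
                inserts[g][""] += w
            continue
        cigar = edlib.align(s, center, mode="NW", task="path")["cigar"]
        qi = 0  # position in s (query)
        tj = 0  # position in center (target)
        pending: list[str] = [""] * (ncol + 1)
        for length, op in _parse_cigar(cigar):
            if op in ("=", "X"):
                for _ in range(length):
                    columns[tj][s[qi]] += w
                    qi += 1
                    tj += 1
            elif op == "D":  # center char absent from s -> gap votes
                for _ in range(length):
                    columns[tj]["-"] += w
                    tj += 1
            elif op == "I":  # extra chars in s -> insertion before column tj
                pending[tj] += s[qi : qi + length]
                qi += length
            else:  # pragma: no cover - edlib emits only =,X,I,D
                raise ValueError(f"unexpected CIGAR op {op!r}")
        for g in range(ncol + 1):
            inserts[g][pending[g]] += w

    out: list[str] = []
    for j in range(ncol + 1):
        seg = _tie_break_insert(inserts[j])
        if seg:
            out.append(seg)
        if j < ncol:
            ch = _tie_break_column(columns[j])
            if ch != "-":
                out.append(ch)
    return ConsensusResult("".join(out), len(strings))


def _parse_cigar(cigar: str):
    """Yield (length, op) pairs from an edlib extended CIGAR string."""
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
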