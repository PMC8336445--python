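"""Greedy higher-order repeat (HOR) inference over a monostring.

A HOR is modelled as a string over the monomer alphabet, so HOR discovery
becomes a grammar-style compression problem: find a string-set whose
decomposition of the monostring minimises orbit(w) + length(Strings).  The
greedy step machinery is

* ``count_nonoverlapping`` — leftmost non-overlapping occurrence count,
* ``substitute``           — replace those occurrences by one new symbol,
* ``run_length_encode``    — collapse runs X...X into X^n, each counted as
  one symbol (tandem HOR arrays collapse to almost nothing),
* ``hor_weight``           — the run-length saving |S*| - |S(h)*| of a
  substitution.

``hor_decompose`` iterates: among the *recurrent* (count >= MinCount),
*short* (|h| <= MaxLength), *heavy* (weight >= MinWeight), non-trivial
candidate substrings containing at least one original monomer symbol it
substitutes the one minimising the run-length-encoded length of the result,
until no candidate remains.  Known ("canonical") HORs can be seeded first;
they are substituted before the greedy loop and kept in the output
unconditionally.  ``super_hor_decompose`` strips degrees from a HOR
decomposition and reruns the loop with relaxed thresholds and without the
monomer-containment requirement, yielding superHORs.  The whole chain is
lossless: recursively expanding symbols and degrees reproduces the input
monostring exactly.

Candidate thresholds are inclusive (count >= MinCount, weight >= MinWeight):
the superHOR defaults MinCount = 2, MinWeight = 2 are meant to admit a
twice-occurring pattern of weight 2, which a strict reading would reject.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .blocks import NON_MONOMERIC_TOKEN

__all__ = [
    "HORDef",
    "HORParams",
    "HORDecomposition",
    "orbit",
    "decomposition_score",
    "run_length_encode",
    "run_length_decode",
    "count_nonoverlapping",
    "substitute",
    "hor_weight",
    "select_hor",
    "hor_decompose",
    "super_hor_decompose",
    "classify_hor_frequency",
    "build_hor_graph",
    "expand",
]

Symbols = tuple[str, ...]


def _as_symbols(s: Iterable[str] | str) -> Symbols:
    """Accept either a plain character string or an iterable of symbols."""
    return tuple(s)


@dataclass
class HORDef:
    """A named HOR with its expansion over the current alphabet.

    ``count`` is the total number of H-blocks in the full expansion of the
    decomposition: top-level occurrences (degrees expanded, an element H^n
    contributes n) plus occurrences nested inside every occurrence of a
    later HOR whose definition contains H.  ``count_top`` keeps the
    top-level-only tally, and ``n_elements`` counts decomposition elements
    before degree expansion; all three conventions appear in published HOR
    tables.  ``weight`` is the run-length saving achieved when the HOR was
    substituted.
    """

    id: str
    expansion: Symbols
    count: int = 0
    count_top: int = 0
    n_elements: int = 0
    weight: int = 0
    freq_class: str | None = None
    is_super: bool = False
    is_canonical: bool = False

    @property
    def length(self) -> int:
        return len(self.expansion)


@dataclass(frozen=True)
class HORParams:
    """Thresholds of the greedy HOR selection."""

    min_count: int = 5
    max_length: int = 30
    min_weight: int = 5
    hor_freq_ceiling: int = 40
    rare_hor_count: int = 10
    super_min_count: int = 2
    super_min_weight: int = 2

    def super_params(self) -> "HORParams":
        return HORParams(
            min_count=self.super_min_count,
            max_length=self.max_length,
            min_weight=self.super_min_weight,
            hor_freq_ceiling=self.hor_freq_ceiling,
            rare_hor_count=self.rare_hor_count,
        )


@dataclass
class HORDecomposition:
    """Result of a (super)HOR decomposition.

    ``symbols`` is the final plain symbol string; ``encoded`` its run-length
    form as (symbol, degree) pairs; ``hors`` the discovered definitions in
    substitution order.
    """

    symbols: Symbols
    hors: list[HORDef] = field(default_factory=list)

    @property
    def encoded(self) -> list[tuple[str, int]]:
        return run_length_encode(self.symbols)[0]

    @property
    def rle_length(self) -> int:
        return run_length_encode(self.symbols)[1]


# ---------------------------------------------------------------------------
# scores


def orbit(parts: Sequence[Iterable[str] | str], strings: Iterable) -> int:
    """Number of member strings forming a Strings-word.

    ``parts`` is the forming sequence; every part must be a member of
    ``strings`` (the word is their concatenation).
    """
    members = {_as_symbols(s) for s in strings}
    for p in parts:
        if _as_symbols(p) not in members:
            raise ValueError(f"{p!r} is not a member of the string-set")
    return len(parts)


def decomposition_score(
    strings: Iterable[Iterable[str] | str],
    parts: Sequence[Iterable[str] | str],
) -> int:
    """orbit(w) + total length of the string-set."""
    strings = [_as_symbols(s) for s in strings]
    return orbit(parts, strings) + sum(len(s) for s in strings)


# ---------------------------------------------------------------------------
# run-length encoding


def run_length_encode(
    s: Iterable[str] | str,
) -> tuple[list[tuple[str, int]], int]:
    """Collapse maximal runs; each X^n counts as a single symbol."""
    out: list[tuple[str, int]] = []
    for sym, grp in itertools.groupby(_as_symbols(s)):
        out.append((sym, sum(1 for _ in grp)))
    return out, len(out)


def run_length_decode(encoded: Iterable[tuple[str, int]]) -> Symbols:
    out: list[str] = []
    for sym, n in encoded:
        out.extend([sym] * n)
    return tuple(out)


def _rle_length(s: Symbols) -> int:
    n = 0
    prev = None
    for sym in s:
        if sym != prev:
            n += 1
            prev = sym
    return n


# ---------------------------------------------------------------------------
# substitution machinery


def count_nonoverlapping(
    s: Iterable[str] | str, h: Iterable[str] | str
) -> tuple[int, list[int]]:
    """Leftmost non-overlapping occurrence count of h in s, with starts."""
    s, h = _as_symbols(s), _as_symbols(h)
    if not h:
        raise ValueError("pattern must be non-empty")
    starts: list[int] = []
    i = 0
    n, m = len(s), len(h)
    while i <= n - m:
        if s[i : i + m] == h:
            starts.append(i)
            i += m
        else:
            i += 1
    return len(starts), starts


def substitute(
    s: Iterable[str] | str, h: Iterable[str] | str, symbol: str
) -> Symbols:
    """Replace leftmost non-overlapping occurrences of h by ``symbol``."""
    s, h = _as_symbols(s), _as_symbols(h)
    if symbol in s:
        raise ValueError(f"symbol {symbol!r} already occurs in the string")
    _, starts = count_nonoverlapping(s, h)
    out: list[str] = []
    i = 0
    starts_set = set(starts)
    while i < len(s):
        if i in starts_set:
            out.append(symbol)
            i += len(h)
        else:
            out.append(s[i])
            i += 1
    return tuple(out)


def hor_weight(s: Iterable[str] | str, h: Iterable[str] | str) -> int:
    """Run-length saving |S*| - |S(h)*| of the h-substitution."""
    s = _as_symbols(s)
    return _rle_length(s) - _rle_length(substitute(s, h, "\0"))


# ---------------------------------------------------------------------------
# greedy selection


def _candidates(
    s: Symbols, params: HORParams, initial_alphabet: frozenset[str] | None
) -> list[Symbols]:
    """Deduplicated candidate substrings passing the cheap filters.

    A first pass counts overlapping occurrences by hashing every substring
    of length 2..MaxLength (an upper bound on the non-overlapping count),
    then survivors are re-counted exactly.
    """
    n = len(s)
    occs: dict[Symbols, int] = {}
    for length in range(2, min(params.max_length, n) + 1):
        for i in range(n - length + 1):
            sub = s[i : i + length]
            occs[sub] = occs.get(sub, 0) + 1
    out = []
    floor = max(params.min_count, 2)  # a repeat must occur at least twice
    for sub, c in occs.items():
        if c < floor:
            continue
        if NON_MONOMERIC_TOKEN in sub:
            continue
        if len(set(sub)) < 2:  # trivial (monorun)
            continue
        if initial_alphabet is not None and not any(
            x in initial_alphabet for x in sub
        ):
            continue
        out.append(sub)
    return out


def select_hor(
    s: Iterable[str] | str,
    params: HORParams | None = None,
    initial_alphabet: Iterable[str] | None = None,
) -> Symbols | None:
    """The next HOR: the recurrent heavy non-trivial substring minimising
    the run-length-encoded length of its substitution.

    Returns None when no candidate passes the thresholds.  Ties resolve to
    the shortest candidate, then the lexicographically smallest expansion.
    """
    if params is None:
        params = HORParams()
    s = _as_symbols(s)
    alpha = frozenset(initial_alphabet) if initial_alphabet is not None else None
    best: tuple | None = None
    best_h: Symbols | None = None
    for h in _candidates(s, params, alpha):
        cnt, _ = count_nonoverlapping(s, h)
        if cnt < max(params.min_count, 2):
            continue
        sub = substitute(s, h, "\0")
        w = _rle_length(s) - _rle_length(sub)
        if w < params.min_weight:
            continue
        key = (_rle_length(sub), len(h), h)
        if best is None or key < best:
            best, best_h = key, h
    return best_h


# ---------------------------------------------------------------------------
# the decomposition loop


def _new_symbol(taken: set[str], is_super: bool, k: int) -> str:
    """Fresh HOR id: a, b, ... for HORs, s1, s2, ... for superHORs."""
    if is_super:
        i = k
        while f"s{i}" in taken:
            i += 1
        return f"s{i}"
    letters = "abcdefghijklmnopqrstuvwxyz"
    if k <= len(letters) and letters[k - 1] not in taken:
        return letters[k - 1]
    i = k
    while f"h{i}" in taken:
        i += 1
    return f"h{i}"


def hor_decompose(
    monostring: Iterable[str] | str,
    params: HORParams | None = None,
    canonical: Sequence[HORDef] | None = None,
    initial_alphabet: Iterable[str] | None = None,
    is_super: bool = False,
) -> HORDecomposition:
    """Greedy HOR decomposition of a monostring.

    Canonical HORs, if given, are substituted first in their stated order,
    are exempt from the count/weight thresholds, and stay in the output even
    at count 0.  The greedy loop then runs to exhaustion.  Every iteration
    asserts the score identity
    score_after = score_before - count*(|h|-1) + |h| and the final result is
    verified to expand losslessly back to the input.
    """
    if params is None:
        params = HORParams()
    s0 = _as_symbols(monostring)
    if initial_alphabet is None:
        initial_alphabet = {x for x in s0 if x != NON_MONOMERIC_TOKEN}
    alpha = frozenset(initial_alphabet)

    s = s0
    hors: list[HORDef] = []
    taken = set(s0)
    alphabet_size = len(set(s0))
    score = len(s) + alphabet_size

    def apply(h: Symbols, hor: HORDef) -> Symbols:
        nonlocal s, score, alphabet_size
        cnt, _ = count_nonoverlapping(s, h)
        before = len(s)
        w = hor_weight(s, h)
        s_new = substitute(s, h, hor.id)
        assert len(s_new) == before - cnt * (len(h) - 1)
        # score(Strings, w) = orbit(w) + length(Strings), where orbit(w) is
        # the plain length of the substituted string and length(Strings)
        # sums |A| unit-length alphabet symbols plus every HOR expansion.
        new_score = len(s_new) + alphabet_size + sum(
            hd.length for hd in hors
        ) + len(h)
        assert new_score == score - cnt * (len(h) - 1) + len(h)
        hor.weight = w
        hors.append(hor)
        taken.add(hor.id)
        s = s_new
        score = new_score
        return s

    if canonical:
        for cdef in canonical:
            h = _as_symbols(cdef.expansion)
            hor = HORDef(
                id=cdef.id,
                expansion=h,
                is_canonical=True,
                is_super=is_super,
            )
            if hor.id in taken:
                raise ValueError(f"canonical HOR id {hor.id!r} already in use")
            apply(h, hor)

    k = len(hors)
    while True:
        h = select_hor(
            s, params, initial_alphabet=None if is_super else alpha
        )
        if h is None:
            break
        k += 1
        hor = HORDef(
            id=_new_symbol(taken, is_super, k),
            expansion=h,
            is_super=is_super,
        )
        apply(h, hor)

    result = HORDecomposition(symbols=s, hors=hors)
    _fill_counts(result)
    if expand(result.symbols, result.hors) != s0:
        raise AssertionError("HOR decomposition is not lossless")
    return result


def _fill_counts(dec: HORDecomposition) -> None:
    counts = {h.id: 0 for h in dec.hors}
    for sym in dec.symbols:
        if sym in counts:
            counts[sym] += 1
    encoded = run_length_encode(dec.symbols)[0]
    for h in dec.hors:
        h.count_top = counts[h.id]
        h.n_elements = sum(1 for sym, _ in encoded if sym == h.id)
    # nested occurrences: a HOR defined later may contain earlier HORs in
    # its expansion; every one of its blocks contributes their blocks too
    total = dict(counts)
    for h in reversed(dec.hors):
        for sym in h.expansion:
            if sym in total:
                total[sym] += total[h.id]
    for h in dec.hors:
        h.count = total[h.id]


def expand(
    symbols: Iterable[str] | str, hors: Sequence[HORDef]
) -> Symbols:
    """Recursively expand HOR symbols back to the original alphabet."""
    defs = {h.id: h.expansion for h in hors}
    out: list[str] = []

    def rec(sym: str) -> None:
        exp = defs.get(sym)
        if exp is None:
            out.append(sym)
        else:
            for x in exp:
                rec(x)

    for sym in _as_symbols(symbols):
        rec(sym)
    return tuple(out)


def super_hor_decompose(
    dec: HORDecomposition, params: HORParams | None = None
) -> HORDecomposition:
    """Infer superHORs from a HOR decomposition.

    Degrees are stripped (every run H^n becomes a single H) and the greedy
    loop is rerun with the relaxed super thresholds and no
    monomer-containment requirement.  The result is lossless with respect
    to the *degree-stripped* string; the degree-bearing HOR decomposition
    is reported alongside, not re-attached.
    """
    if params is None:
        params = HORParams()
    stripped = tuple(sym for sym, _ in run_length_encode(dec.symbols)[0])
    sup = hor_decompose(
        stripped, params.super_params(), is_super=True
    )
    return sup


# ---------------------------------------------------------------------------
# frequency classes and the HOR-graph


def classify_hor_frequency(
    hors: Sequence[HORDef],
    dec: HORDecomposition,
    params: HORParams | None = None,
) -> None:
    """Assign frequent / infrequent / rare in place.

    A HOR is frequent if its H-block count exceeds
    |HORDecomposition| / HORFreqCeiling, where |HORDecomposition| is the
    number of elements of the run-length form; an infrequent HOR is rare if
    its count does not exceed rareHORCount.
    """
    if params is None:
        params = HORParams()
    n_elements = dec.rle_length
    for h in hors:
        if h.count > n_elements / params.hor_freq_ceiling:
            h.freq_class = "frequent"
        elif h.count <= params.rare_hor_count:
            h.freq_class = "rare"
        else:
            h.freq_class = "infrequent"


def monomer_content(
    hor: HORDef, defs: Mapping[str, HORDef]
) -> frozenset[str]:
    """Monomers appearing in the recursive expansion of a HOR."""
    out: set[str] = set()

    def rec(sym: str) -> None:
        d = defs.get(sym)
        if d is None:
            if sym != NON_MONOMERIC_TOKEN:
                out.add(sym)
        else:
            for x in d.expansion:
                rec(x)

    for x in hor.expansion:
        rec(x)
    return frozenset(out)


def build_hor_graph(hors: Sequence[HORDef]) -> nx.Graph:
    """Undirected graph on HORs sharing at least one monomer.

    Each node carries its HORDef; each connected component is annotated
    (node attribute ``primary``) with its primary HOR: the member of
    maximal count, ties broken by lexicographically smallest id.
    """
    defs = {h.id: h for h in hors}
    contents = {h.id: monomer_content(h, defs) for h in hors}
    g = nx.Graph()
    for h in hors:
        g.add_node(h.id, hor=h)
    ids = sorted(defs)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if contents[a] & contents[b]:
                g.add_edge(a, b)
    for comp in nx.connected_components(g):
        primary = min(comp, key=lambda x: (-defs[x].count, x))
        for node in comp:
            g.nodes[node]["primary"] = primary
    return g
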