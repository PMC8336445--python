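import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cenhor.examples import RLE_EXAMPLE, SUBSTITUTION_EXAMPLE, WORKED_WORD_PARTS, \
    WORKED_WORD_SET
from cenhor.hors import (
    HORDecomposition,
    HORDef,
    HORParams,
    build_hor_graph,
    classify_hor_frequency,
    count_nonoverlapping,
    decomposition_score,
    expand,
    hor_decompose,
    hor_weight,
    orbit,
    run_length_decode,
    run_length_encode,
    select_hor,
    substitute,
    super_hor_decompose,
)

symbol_strings = st.text(alphabet="ABCD", min_size=0, max_size=40)

S = SUBSTITUTION_EXAMPLE  # CABDEGFABEGFBDEGFABDEGFDABABDD


# ---------------------------------------------------------------------------
# scores


def test_orbit_of_worked_word():
    assert orbit(WORKED_WORD_PARTS, WORKED_WORD_SET) == 4


def test_orbit_empty_and_singleton():
    assert orbit([], WORKED_WORD_SET) == 0
    assert orbit(["AB"], WORKED_WORD_SET) == 1


def test_orbit_rejects_non_member():
    with pytest.raises(ValueError):
        orbit(["AB", "XY"], WORKED_WORD_SET)


def test_decomposition_score():
    assert decomposition_score(WORKED_WORD_SET, WORKED_WORD_PARTS) == 10
    # an alphabet decomposition scores |S| + |A|
    assert decomposition_score(["A", "B"], list("ABAB")) == 6
    assert decomposition_score([], []) == 0


# ---------------------------------------------------------------------------
# run-length encoding


def test_rle_worked_example():
    enc, n = run_length_encode(RLE_EXAMPLE)
    assert enc == [("A", 1), ("B", 2), ("C", 1), ("A", 3), ("D", 1)]
    assert n == 5


@pytest.mark.parametrize(
    "s,n", [("AAAA", 1), ("", 0), ("ABAB", 4)]
)
def test_rle_lengths(s, n):
    assert run_length_encode(s)[1] == n


@settings(deadline=None, max_examples=200)
@given(symbol_strings)
def test_rle_roundtrip(s):
    enc, n = run_length_encode(s)
    assert run_length_decode(enc) == tuple(s)
    assert n == len(enc)


# ---------------------------------------------------------------------------
# counting and substitution


def test_leftmost_count_worked_example():
    assert count_nonoverlapping("AABBCAAAD", "AA") == (2, [0, 5])


def test_count_absent_pattern():
    assert count_nonoverlapping("ABCD", "XY") == (0, [])


def test_count_in_substitution_example():
    assert count_nonoverlapping(S, "AB")[0] == 5


def test_substitute_ab():
    out = substitute(S, "AB", "h")
    assert "".join(out) == "ChDEGFhEGFBDEGFhDEGFDhhDD"
    assert len(out) == 25
    assert run_length_encode(out)[1] == 23


def test_substitute_egf():
    out = substitute(S, "EGF", "g")
    assert "".join(out) == "CABDgABgBDgABDgDABABDD"
    assert len(out) == 22
    assert run_length_encode(out)[1] == 21


def test_substitute_absent_pattern_is_identity():
    assert substitute(S, "XYZ", "h") == tuple(S)


def test_substitute_inverse_expansion():
    out = substitute(S, "AB", "h")
    assert expand(out, [HORDef(id="h", expansion=("A", "B"))]) == tuple(S)


def test_substitution_length_identity():
    cnt, _ = count_nonoverlapping(S, "AB")
    assert len(substitute(S, "AB", "h")) == len(S) - cnt * (2 - 1)


def test_hor_weight_worked_examples():
    assert run_length_encode(S)[1] == 29
    assert hor_weight(S, "AB") == 29 - 23
    assert hor_weight(S, "EGF") == 29 - 21
    assert hor_weight(S, "XYZ") == 0


def test_three_step_substitution_chain():
    s1 = substitute(S, "EGF", "a")
    assert "".join(s1) == "CABDaABaBDaABDaDABABDD"
    s2 = substitute(s1, "AB", "b")
    assert "".join(s2) == "CbDabaBDabDaDbbDD"
    s3 = substitute(s2, "Da", "c")
    assert "".join(s3) == "CbcbaBcbcDbbDD"
    assert run_length_encode(s3)[0] == [
        ("C", 1), ("b", 1), ("c", 1), ("b", 1), ("a", 1), ("B", 1),
        ("c", 1), ("b", 1), ("c", 1), ("D", 1), ("b", 2), ("D", 2),
    ]


# ---------------------------------------------------------------------------
# greedy selection


def test_select_hor_monorun_returns_none():
    assert select_hor("A" * 50) is None


def test_select_hor_planted_tandem():
    s = "ABC" * 100
    assert select_hor(s) == ("A", "B", "C")


def test_select_hor_matches_exhaustive_oracle():
    params = HORParams(min_count=2, min_weight=1)

    def oracle(s):
        best = None
        n = len(s)
        for length in range(2, min(params.max_length, n) + 1):
            for i in range(n - length + 1):
                h = tuple(s[i : i + length])
                if len(set(h)) < 2:
                    continue
                cnt, _ = count_nonoverlapping(s, h)
                if cnt < 2:
                    continue
                if hor_weight(s, h) < params.min_weight:
                    continue
                key = (run_length_encode(substitute(s, h, "\0"))[1], length, h)
                if best is None or key < best:
                    best = key
        return best[2] if best else None

    for s in ["ABC" * 7, S, "ABABABCDCDCD", "AABBAABBAABB"]:
        assert select_hor(s, params) == oracle(s)


def test_monomer_containment_excludes_hor_only_patterns():
    # after the worked chain, bc repeats but contains no original monomer
    s3 = "CbcbaBcbcDbbDD"
    initial = set("CABDEGF")  # uppercase: original monomers
    assert select_hor(
        s3, HORParams(min_count=2, min_weight=1), initial_alphabet=initial
    ) is None


def test_superhor_pass_finds_bc():
    dec = HORDecomposition(symbols=tuple("CbcbaBcbcDbbDD"))
    sup = super_hor_decompose(dec)
    assert ("b", "c") in [h.expansion for h in sup.hors]
    assert all(h.is_super for h in sup.hors)


def test_superhor_degree_stripping_compacts_runs():
    # g a^3 g a^15 g a^6 g a^4 g a^5 g a^39 strips to (ga)^6
    symbols = []
    for n in (3, 15, 6, 4, 5, 39):
        symbols.append("g")
        symbols.extend(["a"] * n)
    dec = HORDecomposition(symbols=tuple(symbols))
    sup = super_hor_decompose(dec)
    assert [h.expansion for h in sup.hors] == [("g", "a")]
    assert sup.symbols == (sup.hors[0].id,) * 6


# ---------------------------------------------------------------------------
# the decomposition loop


def test_decompose_no_recurrent_substring():
    dec = hor_decompose("ABCDEFG")
    assert dec.hors == []
    assert dec.symbols == tuple("ABCDEFG")


def test_decompose_planted_tandem():
    dec = hor_decompose("ABC" * 100)
    assert len(dec.hors) == 1
    assert dec.hors[0].expansion == ("A", "B", "C")
    assert dec.hors[0].count == 100
    assert dec.rle_length == 1
    assert expand(dec.symbols, dec.hors) == tuple("ABC" * 100)


@settings(deadline=None, max_examples=100)
@given(symbol_strings)
def test_decompose_lossless_on_random_strings(s):
    params = HORParams(min_count=2, min_weight=1)
    dec = hor_decompose(s, params)
    assert expand(dec.symbols, dec.hors) == tuple(s)


def test_decompose_skips_nonmonomeric_token():
    s = list("ABAB") + ["?"] + list("ABAB")
    dec = hor_decompose(s, HORParams(min_count=2, min_weight=1))
    for h in dec.hors:
        assert "?" not in h.expansion
    assert expand(dec.symbols, dec.hors) == tuple(s)


def test_canonical_hors_seeded_and_kept():
    canonical = [HORDef(id="k", expansion=tuple("XY"))]
    dec = hor_decompose(
        "ABAB", HORParams(min_count=2, min_weight=1), canonical=canonical
    )
    ids = [h.id for h in dec.hors]
    assert ids[0] == "k"
    k = dec.hors[0]
    assert k.is_canonical and k.count == 0  # kept despite zero occurrences
    assert expand(dec.symbols, dec.hors) == tuple("ABAB")


def test_canonical_hors_substituted_first():
    canonical = [HORDef(id="k", expansion=tuple("AB"))]
    dec = hor_decompose(
        "ABCABCABC", HORParams(min_count=2, min_weight=1), canonical=canonical
    )
    assert dec.hors[0].id == "k"
    assert dec.hors[0].count == 3
    assert expand(dec.symbols, dec.hors) == tuple("ABCABCABC")


# ---------------------------------------------------------------------------
# frequency classes


def _dec_of(symbols):
    return HORDecomposition(symbols=tuple(symbols))


def test_hor_frequency_classes():
    params = HORParams()
    # 401 run-length elements -> frequency threshold 401/40 ~ 10.0
    dec = _dec_of(["a", "X"] * 11 + ["X", "Y"] * 190)
    assert dec.rle_length == 401
    h = HORDef(id="a", expansion=("X", "Y"), count=11)
    classify_hor_frequency([h], dec, params)
    assert h.freq_class == "frequent"

    rare = HORDef(id="b", expansion=("X", "Y"), count=10)
    classify_hor_frequency([rare], dec, params)
    assert rare.freq_class == "rare"  # boundary: does not exceed 10


def test_hor_frequency_infrequent_between_thresholds():
    params = HORParams(hor_freq_ceiling=2, rare_hor_count=3)
    h = HORDef(id="a", expansion=("X", "Y"), count=4)
    dec = _dec_of(["X", "Y"] * 10)  # 20 elements, threshold 10
    classify_hor_frequency([h], dec, params)
    assert h.freq_class == "infrequent"


# ---------------------------------------------------------------------------
# HOR-graph


def test_hor_graph_components_and_primaries():
    hors = [
        HORDef(id="u", expansion=("A", "B"), count=5),
        HORDef(id="v", expansion=("B", "C"), count=9),
        HORDef(id="w", expansion=("D", "E"), count=2),
    ]
    g = build_hor_graph(hors)
    import networkx as nx

    comps = sorted(sorted(c) for c in nx.connected_components(g))
    assert comps == [["u", "v"], ["w"]]
    assert g.nodes["u"]["primary"] == "v"
    assert g.nodes["w"]["primary"] == "w"


def test_hor_graph_single_hor_is_primary():
    g = build_hor_graph([HORDef(id="u", expansion=("A", "B"), count=1)])
    assert g.nodes["u"]["primary"] == "u"


def test_hor_graph_resolves_nested_expansions():
    hors = [
        HORDef(id="a", expansion=("A", "B"), count=10),
        HORDef(id="b", expansion=("a", "C"), count=3),  # contains A, B via a
    ]
    g = build_hor_graph(hors)
    assert g.has_edge("a", "b")
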