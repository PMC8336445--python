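import math

import numpy as np
import pytest

from cenhor.align import consensus, divergence, edit_distance
from cenhor.blocks import decompose
from cenhor.monomers import (
    ConvergenceError,
    MonomerGenParams,
    build_block_graph,
    detect_hybrids,
    generate_monomers,
    monomer_stats,
    resolves,
)


def _rand_seq(rng, n):
    return rng.choice(np.frombuffer(b"ACGT", np.uint8), n).tobytes().decode()


def _noisy(rng, s, n_subs):
    t = list(s)
    for p in rng.choice(len(s), n_subs, replace=False):
        t[p] = "ACGT"[rng.integers(0, 4)]
    return "".join(t)


# ---------------------------------------------------------------------------
# block-graph


def test_block_graph_identical_pair():
    g = build_block_graph(["ACGTACGTAC"] * 2, 0.025)
    assert set(g.edges) == {(0, 1)}


def test_block_graph_distant_blocks_unconnected():
    rng = np.random.default_rng(1)
    s = _rand_seq(rng, 100)
    t = _noisy(rng, s, 10)  # 10% divergence, threshold 2.5%
    g = build_block_graph([s, t], 0.025)
    assert g.number_of_edges() == 0


def test_block_graph_two_clusters_two_components():
    import networkx as nx

    rng = np.random.default_rng(2)
    a, b = _rand_seq(rng, 171), _rand_seq(rng, 171)
    while divergence(a, b) < 0.25:
        b = _rand_seq(rng, 171)
    seqs = [_noisy(rng, a, 1) for _ in range(60)] + [
        _noisy(rng, b, 1) for _ in range(40)
    ]
    g = build_block_graph(seqs, 0.025)
    comps = sorted(len(c) for c in nx.connected_components(g))
    assert comps == [40, 60]


def test_block_graph_sketch_equals_bruteforce():
    rng = np.random.default_rng(3)
    base = _rand_seq(rng, 80)
    seqs = [_noisy(rng, base, int(k)) for k in rng.integers(0, 12, 40)]
    g1 = build_block_graph(seqs, 0.05, method="sketch")
    g2 = build_block_graph(seqs, 0.05, method="bruteforce")
    assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


def test_block_graph_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        build_block_graph(["A"], 0.0)


# ---------------------------------------------------------------------------
# generator


def test_exact_repeat_single_monomer_one_iteration():
    m = "ACGTTGCAATGCACGGTATTGCAATGGCATCAA" * 5 + "ACGTTG"  # 171 bp
    assert len(m) == 171
    seq = m * 50
    monomers, blocks, log = generate_monomers(seq, m, MonomerGenParams())
    assert set(monomers) == {"m1"}
    assert monomers["m1"] == m
    assert len(blocks) == 50
    assert all(b.status == "resolved" for b in blocks)
    assert len(log) == 1


def test_generator_recovers_planted_monomers(small_inference):
    seq, truth, monomers, blocks, log = small_inference
    stats = monomer_stats(monomers, blocks, seq)
    frequent = [m for m in stats.values() if m.freq_class == "frequent"]
    assert len(frequent) == 3
    from cenhor.sim import match_monomers

    matches = match_monomers(
        [m.sequence for m in frequent], truth.monomers
    )
    assert max(d for _, _, d in matches) <= 0.01


def test_generator_termination_satisfies_resolves(small_inference):
    _, _, _, blocks, _ = small_inference
    assert resolves(blocks, MonomerGenParams().fraction_resolved_blocks)


def test_generator_fixed_point(small_inference):
    seq, _, monomers, blocks, _ = small_inference
    for mid, mseq in monomers.items():
        mine = [
            b.sequence(seq)
            for b in blocks
            if b.best_monomer == mid and b.status == "resolved"
        ]
        if mine:
            assert consensus(mine).consensus == mseq


def test_generator_monotone_resolution(small_inference):
    _, _, _, _, log = small_inference
    res = [row["resolved"] for row in log]
    assert res == sorted(res)


def test_generator_nonconvergence_raises_with_log():
    rng = np.random.default_rng(9)
    a, b = _rand_seq(rng, 40), _rand_seq(rng, 40)
    params = MonomerGenParams(length=40, max_iterations=1)
    with pytest.raises(ConvergenceError) as exc:
        generate_monomers((a + b) * 20, a, params)
    assert len(exc.value.iteration_log) == 1


def test_generator_rejects_bad_initial_length():
    with pytest.raises(ValueError):
        generate_monomers("ACGT" * 100, "ACGT" * 10, MonomerGenParams())


# ---------------------------------------------------------------------------
# statistics


def test_monomer_stats_frequency_classes():
    m1 = "ACGTTGCAATGCACGGTATT"
    m2 = "TTGACCGGTAACTGACCTGA"
    # 12 copies of m1, 5 of m2: threshold 17/3 ~ 5.7, so m1 is frequent
    # while m2 (count 5, not exceeding the threshold) is infrequent, and
    # count 5 <= rareMonomerCount makes it rare (boundary inclusive)
    seq = m1 * 12 + m2 * 5
    blocks = decompose(seq, {"m1": m1, "m2": m2})
    stats = monomer_stats(
        {"m1": m1, "m2": m2}, blocks, seq,
        MonomerGenParams(length=20, freq_ceiling=3),
    )
    assert stats["m1"].freq_class == "frequent"
    assert stats["m2"].freq_class == "rare"
    assert stats["m1"].count == 12 and stats["m2"].count == 5
    assert stats["m1"].radius == 0
    assert stats["m1"].separation == edit_distance(m1, m2)
    assert stats["m1"].separation_ratio == math.inf  # radius 0 sentinel


def test_monomer_stats_single_monomer_no_separation():
    m = "ACGTTGCAAT"
    blocks = decompose(m * 4, {"M": m})
    stats = monomer_stats({"M": m}, blocks, m * 4, MonomerGenParams(length=10))
    assert stats["M"].separation is None
    assert stats["M"].separation_ratio is None


# ---------------------------------------------------------------------------
# hybrids


@pytest.fixture(scope="module")
def hybrid_parents():
    rng = np.random.default_rng(42)
    return _rand_seq(rng, 171), _rand_seq(rng, 171)


def test_exact_hybrid_detected_at_zero_divergence(hybrid_parents):
    x, y = hybrid_parents
    m = x[:68] + y[-103:]
    ann = detect_hybrids({"M": m}, {"X": x, "Y": y})
    assert set(ann) == {"M"}
    a = ann["M"]
    assert a.divergence == 0.0
    assert (a.x, a.y) == ("X", "Y")
    assert a.i + a.j == len(m)
    assert x[: a.i] + y[-a.j :] == m


def test_distant_candidate_not_annotated(hybrid_parents):
    x, y = hybrid_parents
    rng = np.random.default_rng(43)
    m = _rand_seq(rng, 171)
    assert detect_hybrids({"M": m}, {"X": x, "Y": y}) == {}


def test_hybrid_with_one_substitution(hybrid_parents):
    x, y = hybrid_parents
    m = list(x[:68] + y[-103:])
    m[30] = "A" if m[30] != "A" else "C"
    ann = detect_hybrids({"M": "".join(m)}, {"X": x, "Y": y})
    assert ann["M"].divergence == pytest.approx(1 / 171)


def test_hybrid_requires_parents():
    with pytest.raises(ValueError):
        detect_hybrids({"M": "ACGT"}, {})
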