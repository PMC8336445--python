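"""Synthetic nested tandem repeats with known ground truth.

Real satellite arrays are tandem arrays of a higher-order repeat (HOR) unit
built from a small alphabet of diverged ~171 bp monomers: HOR copies are
95-100% identical to each other while the monomers within a unit are only
65-88% identical.  The simulator emulates exactly that structure:

* a monomer alphabet is generated by mutating a common random ancestor
  (mirroring the shared descent of alpha-satellite monomers) and accepted
  only if all pairwise divergences fall within 20% of the requested
  inter-monomer divergence;
* a HOR pattern over that alphabet is tandemly repeated ``n_units`` times,
  each monomer copy receiving independent substitutions and short indels
  (indels capped at 3 bp so the array stays length-uniform);
* optional variant units (alternative patterns at a given frequency) and
  non-monomeric insertions (random segments, e.g. LINE/Alu stand-ins) are
  planted at recorded positions.

Everything is driven by one integer seed; identical specs produce
byte-identical sequences.  The emitted ground truth tiles the sequence
exactly, which is what truth-aware evaluation (``truth_compare``) relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .align import divergence
from .blocks import Block

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "TruthBlock",
    "simulate_array",
    "truth_compare",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of one synthetic satellite array."""

    n_monomers: int
    monomer_length: int = 171
    inter_monomer_divergence: float = 0.25
    hor_pattern: tuple[int, ...] | None = None  # default: 0..n_monomers-1
    n_units: int = 100
    sub_rate: float = 0.009
    indel_rate: float = 0.001
    variant_units: tuple[tuple[tuple[int, ...], float], ...] = ()
    insertions: tuple[tuple[int, int], ...] = ()  # (length, after unit idx)
    seed: int = 0

    def pattern(self) -> tuple[int, ...]:
        if self.hor_pattern is not None:
            return tuple(self.hor_pattern)
        return tuple(range(self.n_monomers))

    def validate(self) -> None:
        if self.n_monomers < 1 or self.n_units < 1:
            raise ValueError("need at least one monomer and one unit")
        if not self.pattern():
            raise ValueError("HOR pattern must be non-empty")
        if any(i >= self.n_monomers or i < 0 for i in self.pattern()):
            raise ValueError("pattern indexes an unknown monomer")
        for rate in (self.sub_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("mutation rates must be in [0, 1]")
        for _, freq in self.variant_units:
            if not 0 <= freq <= 1:
                raise ValueError("variant frequencies must be in [0, 1]")
        if self.n_monomers > 1 and self.inter_monomer_divergence <= 0:
            raise ValueError(
                "inter_monomer_divergence must be positive for >1 monomer"
            )


@dataclass(frozen=True)
class TruthBlock:
    start: int
    end: int
    monomer: int  # index into GroundTruth.monomers, -1 for an insertion
    unit: int


@dataclass
class GroundTruth:
    """Planted monomers, per-block intervals and insertion intervals."""

    monomers: list[str]
    blocks: list[TruthBlock] = field(default_factory=list)
    insertions: list[tuple[int, int]] = field(default_factory=list)
    unit_patterns: list[tuple[int, ...]] = field(default_factory=list)

    def tiling_length(self) -> int:
        return sum(b.end - b.start for b in self.blocks)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, n).tobytes().decode()


def _mutate(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> str:
    """Independent per-base substitutions and short (<= 3 bp) indels."""
    out: list[str] = []
    for ch in seq:
        r = rng.random()
        if r < sub_rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(0, 3)])
        elif r < sub_rate + indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                continue  # deletion of this base (size collapsed to 1)
            out.append(ch)
            out.append(_random_seq(rng, size))
        else:
            out.append(ch)
    return "".join(out)


def _sample_alphabet(
    rng: np.random.Generator, spec: SimulationSpec, max_tries: int = 200
) -> list[str]:
    """Monomers descended from one ancestor, with pairwise divergence in
    inter_monomer_divergence +- 20% of itself (rejection sampling).

    Monomers are accepted incrementally: each draw is kept only if its
    divergence to every accepted monomer falls inside the window, which
    keeps the acceptance probability workable for large alphabets.
    """
    if spec.n_monomers == 1:
        return [_random_seq(rng, spec.monomer_length)]
    d = spec.inter_monomer_divergence
    lo, hi = 0.8 * d, 1.2 * d
    # two branches mutated at per-base rate r diverge by a bit less than 2r
    # (back-mutations and alignment slack); the factor recentres the window
    rate = d / 2 * 1.15
    for _ in range(5):
        ancestor = _random_seq(rng, spec.monomer_length)
        monomers: list[str] = []
        for _ in range(spec.n_monomers):
            for _ in range(max_tries):
                cand = _mutate(rng, ancestor, rate, rate * 0.05)
                if all(lo <= divergence(cand, m) <= hi for m in monomers):
                    monomers.append(cand)
                    break
            else:
                break
        if len(monomers) == spec.n_monomers:
            return monomers
    raise RuntimeError(
        "could not satisfy the inter-monomer divergence constraint; "
        "widen it or lower n_monomers"
    )


def simulate_array(spec: SimulationSpec) -> tuple[str, GroundTruth]:
    """Emit one synthetic satellite array and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    monomers = _sample_alphabet(rng, spec)
    truth = GroundTruth(monomers=monomers)

    variants = list(spec.variant_units)
    insert_after = {}
    for length, unit in spec.insertions:
        insert_after.setdefault(unit, []).append(length)

    chunks: list[str] = []
    pos = 0
    for u in range(spec.n_units):
        pattern = spec.pattern()
        for vpat, freq in variants:
            if rng.random() < freq:
                pattern = tuple(vpat)
                break
        truth.unit_patterns.append(pattern)
        for mi in pattern:
            copy = _mutate(rng, monomers[mi], spec.sub_rate, spec.indel_rate)
            chunks.append(copy)
            truth.blocks.append(TruthBlock(pos, pos + len(copy), mi, u))
            pos += len(copy)
        for length in insert_after.get(u, ()):
            ins = _random_seq(rng, length)
            chunks.append(ins)
            truth.insertions.append((pos, pos + length))
            truth.blocks.append(TruthBlock(pos, pos + length, -1, u))
            pos += length
    return "".join(chunks), truth


# ---------------------------------------------------------------------------
# evaluation against truth


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def match_monomers(
    predicted: Sequence[str], truth: Sequence[str]
) -> list[tuple[int, int, float]]:
    """Best bipartite matching of predicted to true monomers by divergence.

    Returns (predicted index, truth index, divergence) triples.
    """
    if not predicted or not truth:
        return []
    cost = np.array(
        [[divergence(p, t) for t in truth] for p in predicted]
    )
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c), float(cost[r, c])) for r, c in zip(rows, cols)]


def truth_compare(
    pred_blocks: Sequence[Block],
    pred_monomers: Sequence[str],
    truth: GroundTruth,
    min_overlap: float = 0.5,
) -> dict:
    """Precision/recall of predicted blocks and matched monomer divergences.

    A predicted block matches a truth block when their reciprocal overlap is
    at least ``min_overlap``.  The phase flag is raised when matched blocks
    are systematically offset (non-zero median start offset), which happens
    when the prediction is locked to a different monomer phase.
    """
    monomer_matches = match_monomers(pred_monomers, truth.monomers)

    ti = 0
    matched = 0
    offsets: list[int] = []
    truth_hit = [False] * len(truth.blocks)
    for pb in pred_blocks:
        while ti < len(truth.blocks) and truth.blocks[ti].end <= pb.start:
            ti += 1
        k = ti
        best = None
        while k < len(truth.blocks) and truth.blocks[k].start < pb.end:
            ov = _reciprocal_overlap(
                (pb.start, pb.end),
                (truth.blocks[k].start, truth.blocks[k].end),
            )
            if ov >= min_overlap and (best is None or ov > best[0]):
                best = (ov, k)
            k += 1
        if best is not None:
            matched += 1
            truth_hit[best[1]] = True
            offsets.append(pb.start - truth.blocks[best[1]].start)
    precision = matched / len(pred_blocks) if pred_blocks else 0.0
    recall = sum(truth_hit) / len(truth.blocks) if truth.blocks else 0.0
    phase_offset = int(np.median(offsets)) if offsets else 0
    return {
        "precision": precision,
        "recall": recall,
        "phase_offset": phase_offset,
        "phase_flag": phase_offset != 0,
        "monomer_matches": monomer_matches,
        "max_matched_divergence": max(
            (d for _, _, d in monomer_matches), default=None
        ),
    }
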