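# cenhor

Annotation of nested tandem repeats in satellite arrays: monomer inference,
higher-order repeat (HOR) decomposition, and repeat graphs.

## The problem

Centromeric alpha-satellite arrays are extra-long nested tandem repeats:
~171 bp **monomers** (65–88% identical to each other) are organised into
**HOR** units that repeat thousands of times with only a few percent
divergence between copies. Annotating a newly assembled centromere therefore
means answering two questions:

1. **Monomer inference** — find a minimal, length-uniform monomer set
   `Monomers` that *resolves* the array: decomposing the array against the
   set leaves more than `FractionResolvedBlocks` (default 0.95) of blocks
   within `maxResolvedDivergence` (default 5%) of their best monomer, with
   every remaining block non-monomeric (divergence > `maxDivergence`, 40%).
2. **HOR inference** — rewrite the array as a *monostring* over the monomer
   alphabet (plus a `?` token for non-monomeric blocks) and find a string
   set `Strings` minimising `score(Strings, w) = orbit(w) + length(Strings)`
   over all decompositions `w` of the monostring; the members of an optimal
   set are the HORs.

`cenhor` implements both: an iterative **monomer generator** that grows the
monomer set from a single consensus seed by clustering unresolved blocks
(block-graph components) and taking component consensi, and a greedy **HOR
decomposer** that repeatedly substitutes the recurrent, heavy, non-trivial
substring `h` minimising the run-length-encoded length `|S(h)*|` of the
substituted string. Substituting `h` changes the score by exactly
`-count_S(h)·(|h|-1) + |h|`, which the implementation asserts at every
step; the full decomposition (HORs, superHORs, degrees, canonical seeds)
expands losslessly back to the input monostring. On top of these sit
monomer statistics (count, radius, separation, separation ratio, frequency
class), hybrid-monomer detection (`X(i)+Y(j)` prefix/suffix joins of
frequent monomers), monomer-set shifting, superHOR inference, and the
HOR-graph with its per-component primary HOR.

A bundled simulator generates nested tandem repeats with known ground truth
(planted monomer alphabet, HOR pattern, per-copy mutations, variant units,
non-monomeric insertions), so the whole pipeline is testable without any
external data.

## Worked example

```python
from cenhor import (SimulationSpec, simulate_array, consensus,
                    generate_monomers, MonomerGenParams, monomer_stats,
                    to_monostring, hor_decompose)
from cenhor.io import format_hor_string

spec = SimulationSpec(n_monomers=3, n_units=60, seed=7)
seq, truth = simulate_array(spec)          # 30 972 bp, 180 planted blocks

init = consensus(truth.monomers).consensus
monomers, blocks, log = generate_monomers(seq, init, MonomerGenParams())
for m in monomer_stats(monomers, blocks, seq).values():
    print(m.id, m.freq_class, m.count, m.radius, m.separation)

dec = hor_decompose(to_monostring(blocks).symbols)
for h in dec.hors:
    print("HOR", h.id, "=", " ".join(h.expansion), "count", h.count)
print("decomposition:", format_hor_string(dec.encoded))
```

prints

```
m2 frequent 60 4 38
m3 frequent 60 5 45
m4 frequent 60 5 38
HOR a = m3 m4 m2 count 60
decomposition: a^60^
```

Three frequent monomers are recovered (counts of 60 out of 180 blocks;
radius 4–5 edits against separations of ~40, i.e. cleanly separated
clusters), and the greedy decomposer collapses the whole monostring into a
single 3-monomer HOR repeated 60 times — the planted unit, up to the
rotation fixed by the initial consensus.

The same pipeline is available from the shell:

```sh
cenhor simulate --n-monomers 3 --n-units 60 --seed 7 --out-prefix sim
cenhor all sim.fasta init.fasta --out-prefix run   # monomers + blocks + HORs
```

which writes the monomer FASTA (`id|class|count|radius|separation`
headers), the block decomposition TSV, the iteration log, the run-length
HOR/superHOR strings, the HOR-graph (DOT + TSV) and a JSON run manifest
with per-file checksums.

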