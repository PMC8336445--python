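"""Desk-scale example inputs used in the documentation and tests.

Two groups of constants live here:

* tiny abstract symbol strings that exercise the substitution machinery
  (orbit, run-length encoding, h-substitution) with hand-checkable results;
* the published HOR-level annotation of the alpha-satellite array on the
  human X chromosome (cenX, the DXZ1 array): its eight HORs over the
  monomer alphabet A..L (plus the infrequent monomer N), their block counts,
  and the full run-length HOR decomposition string, including the single
  LINE retrotransposon insertion that interrupts the array.  This is the
  standard desk-scale reference for HOR tooling: the array has ~18 000
  monomers organised into ~1500 mostly 12-monomer HOR units.
"""

from __future__ import annotations

from .hors import HORDef

__all__ = [
    "WORKED_WORD",
    "WORKED_WORD_SET",
    "WORKED_WORD_PARTS",
    "RLE_EXAMPLE",
    "COUNT_EXAMPLE",
    "SUBSTITUTION_EXAMPLE",
    "SHIFT_EXAMPLE_MONOMERS",
    "SHIFT_EXAMPLE_REPEAT",
    "CENX_MONOMERS",
    "CENX_HORS",
    "CENX_HOR_DECOMPOSITION",
    "CENX_SUPERHOR_DECOMPOSITION",
    "cenx_hor_defs",
]

#: A word over the string-set {AB, CD, BD} together with its forming parts.
WORKED_WORD = "ABBDCDAB"
WORKED_WORD_SET = ("AB", "CD", "BD")
WORKED_WORD_PARTS = ("AB", "BD", "CD", "AB")

#: Run-length encoding example: collapses to AB^2CA^3D (5 symbols).
RLE_EXAMPLE = "ABBCAAAD"

#: Leftmost non-overlapping counting example: AA occurs twice, at 0 and 5.
COUNT_EXAMPLE = "AABBCAAAD"

#: The 30-symbol string on which the greedy substitution chain is
#: illustrated (substituting EGF, then AB, then Da).
SUBSTITUTION_EXAMPLE = "CABDEGFABEGFBDEGFABDEGFDABABDD"

#: Toy nested tandem repeat for the shifted-monomer construction: three
#: 4 bp "monomers" organised into one "HOR"; shifting their start
#: positions by 2 nt yields the hybrid set {GTAA, CTTG, GTAG}.
SHIFT_EXAMPLE_MONOMERS = {"p": "AGGT", "q": "AACT", "r": "TGGT"}
SHIFT_EXAMPLE_REPEAT = "AGGTAACTTGGT"

#: Monomer alphabet of the cenX HOR table (12 frequent monomers A..L of
#: the canonical DXZ1 unit, plus the infrequent monomer N).
CENX_MONOMERS = tuple("ABCDEFGHIJKLN")

#: The eight cenX HORs: name -> (expansion over monomers and earlier HORs,
#: H-block count).  The canonical 12-monomer unit is ``a``.
CENX_HORS: tuple[tuple[str, str, int], ...] = (
    ("a", "GFDECBALKJIH", 1482),
    ("b", "aGFDECBA", 20),
    ("c", "KJIHa", 18),
    ("d", "bLKJ", 8),
    ("e", "NIH", 8),
    ("f", "Lc", 9),
    ("g", "Gc", 8),
    ("h", "bL", 7),
)

#: The published cenX HOR decomposition in the run-length dialect (the
#: LINE insertion appears as the inline _LINE_ token).  Its run-length
#: encoding has 94 symbols.
CENX_HOR_DECOMPOSITION = (
    "fa^114^da^180^GFECBAfa^33^f^3^a^2^fa^59^hKJBAfa^144^"
    "ga^3^ga^15^ga^6^ga^4^ga^5^ga^39^bebea^12^hea^7^hea^18^hea^7^hea^17^"
    "hea^7^bea^239^bFEDCBAfa^223^ga^3^ga^5^da^10^d^4^a^10^dada^127^"
    "b_LINE_ca^133^GEDCBAfa^21^hKJ"
)

#: The published cenX superHOR decomposition (degrees stripped).
CENX_SUPERHOR_DECOMPOSITION = (
    "fadaGFECBAfafahKJBAfagabebeaheabFEDCBAfagadab_LINE_caGEDCBAfahKJ"
)


def cenx_hor_defs() -> list[HORDef]:
    """The eight cenX HORs as HORDef objects (counts filled in)."""
    return [
        HORDef(id=name, expansion=tuple(exp), count=count)
        for name, exp, count in CENX_HORS
    ]
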