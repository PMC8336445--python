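"""Readers and writers for the on-disk formats.

FASTA in/out goes through Biopython; tabular outputs (block decomposition,
HOR tables, iteration logs, truth) are TSV via pandas; repeat graphs are
exported as DOT and TSV edge lists; (super)HOR strings use a compact
run-length dialect; and every run can be summarised in a JSON manifest with
per-file checksums.

The HOR-string dialect: one character per symbol, powers written ``a^114^``
(caret-free ``a114`` is accepted on input), multi-character symbols wrapped
in underscores (``b_LINE_c``), whitespace ignored.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .blocks import Block, DecompositionParams, NON_MONOMERIC_TOKEN
from .hors import HORDef
from .monomers import Monomer

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_monomer_fasta",
    "write_decomposition_tsv",
    "read_decomposition_tsv",
    "write_iteration_log",
    "write_hor_tsv",
    "write_bed",
    "write_dot",
    "write_edge_tsv",
    "parse_hor_string",
    "format_hor_string",
    "RunManifest",
]

_DECOMP_COLUMNS = [
    "seq_id",
    "monomer_id",
    "start",
    "end",
    "div1_pct",
    "second_monomer_id",
    "div2_pct",
    "status",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, uppercased sequence) records; duplicate ids rejected."""
    path = Path(path)
    _prescan_fasta(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _prescan_fasta(path: Path) -> None:
    """Reject text before the first header, reporting the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected a FASTA header line"
                )
            return


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_monomer_fasta(
    path: str | Path, monomers: Mapping[str, Monomer]
) -> None:
    """Monomer set with ``id|class|count|radius|separation`` headers."""
    def fmt(v) -> str:
        return "." if v is None else str(v)

    with open(path, "w") as fh:
        for mid in sorted(monomers):
            m = monomers[mid]
            fh.write(
                f">{m.id}|{fmt(m.freq_class)}|{m.count}|{fmt(m.radius)}|"
                f"{fmt(m.separation)}\n"
            )
            for i in range(0, len(m.sequence), 80):
                fh.write(m.sequence[i : i + 80] + "\n")


def write_decomposition_tsv(
    path: str | Path, blocks: Sequence[Block]
) -> None:
    """One row per block; 0-based half-open coordinates, divergences in %."""
    rows = [
        {
            "seq_id": b.seq_id,
            "monomer_id": b.best_monomer,
            "start": b.start,
            "end": b.end,
            "div1_pct": f"{100 * b.div1:.2f}",
            "second_monomer_id": b.second_monomer or ".",
            "div2_pct": "." if b.div2 is None else f"{100 * b.div2:.2f}",
            "status": b.status,
        }
        for b in blocks
    ]
    pd.DataFrame(rows, columns=_DECOMP_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_decomposition_tsv(path: str | Path) -> list[Block]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    blocks: list[Block] = []
    for _, r in df.iterrows():
        blocks.append(
            Block(
                seq_id=r["seq_id"],
                start=int(r["start"]),
                end=int(r["end"]),
                best_monomer=r["monomer_id"],
                second_monomer=None
                if r["second_monomer_id"] == "."
                else r["second_monomer_id"],
                div1=float(r["div1_pct"]) / 100,
                div2=None
                if r["div2_pct"] == "."
                else float(r["div2_pct"]) / 100,
                status=r["status"],
            )
        )
    return blocks


def write_iteration_log(path: str | Path, log: Sequence[dict]) -> None:
    pd.DataFrame(log).to_csv(path, sep="\t", index=False, na_rep=".")


def write_hor_tsv(path: str | Path, hors: Sequence[HORDef]) -> None:
    rows = [
        {
            "id": h.id,
            "expansion": format_hor_string(
                [(x, 1) for x in h.expansion], collapse=False
            ),
            "length": h.length,
            "count": h.count,
            "weight": h.weight,
            "class": h.freq_class or ".",
            "is_super": h.is_super,
            "is_canonical": h.is_canonical,
        }
        for h in hors
    ]
    pd.DataFrame(
        rows,
        columns=[
            "id", "expansion", "length", "count", "weight", "class",
            "is_super", "is_canonical",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_bed(
    path: str | Path, intervals: Iterable[tuple[str, int, int, str]]
) -> None:
    """0-based half-open BED with a name column."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_dot(path: str | Path, graph) -> None:
    """Minimal DOT export with edge weight labels."""
    directed = graph.is_directed()
    kind, arrow = ("digraph", "->") if directed else ("graph", "--")
    with open(path, "w") as fh:
        fh.write(kind + " G {\n")
        for node in sorted(graph.nodes):
            fh.write(f'  "{node}";\n')
        for u, v, data in sorted(graph.edges(data=True)):
            w = data.get("weight")
            label = f' [label="{w}"]' if w is not None else ""
            fh.write(f'  "{u}" {arrow} "{v}"{label};\n')
        fh.write("}\n")


def write_edge_tsv(path: str | Path, graph) -> None:
    rows = [
        {"src": u, "dst": v, "weight": d.get("weight", 1)}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["src", "dst", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# HOR-string dialect

_TOKEN_RE = re.compile(
    r"\s+"                      # ignored whitespace
    r"|_(?P<named>[^_]+)_"      # multi-character symbol, e.g. _LINE_
    r"|(?P<sym>[^\s^_])"        # single-character symbol
)
_POWER_RE = re.compile(r"\^?(?P<n>\d+)\^?")


def parse_hor_string(
    text: str, alphabet: Iterable[str] | None = None
) -> list[tuple[str, int]]:
    """Parse a run-length HOR string into (symbol, degree) pairs.

    Powers may be written ``a^114^``, ``a^114`` or ``a114``; symbols longer
    than one character are wrapped in underscores (``b_LINE_c``).  When an
    ``alphabet`` is given, unknown symbols raise a ValueError naming them.
    """
    allowed = set(alphabet) if alphabet is not None else None
    out: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ValueError(f"cannot parse HOR string at position {pos}")
        pos = m.end()
        sym = m.group("named") or m.group("sym")
        if sym is None:
            continue  # whitespace
        degree = 1
        pm = _POWER_RE.match(text, pos)
        if pm and sym not in "0123456789":
            degree = int(pm.group("n"))
            pos = pm.end()
        if allowed is not None and sym != NON_MONOMERIC_TOKEN \
                and sym not in allowed:
            raise ValueError(f"unknown symbol {sym!r} in HOR string")
        out.append((sym, degree))
    return out


def format_hor_string(
    encoded: Sequence[tuple[str, int]], collapse: bool = True
) -> str:
    """Inverse of :func:`parse_hor_string` (powers as ``a^114^``)."""
    parts: list[str] = []
    for sym, n in encoded:
        tok = sym if len(sym) == 1 else f"_{sym}_"
        if n == 1 or not collapse:
            parts.append(tok * n if not collapse else tok)
        else:
            parts.append(f"{tok}^{n}^")
    return "".join(parts)


# ---------------------------------------------------------------------------
# run manifest


@dataclass
class RunManifest:
    """Inputs, parameters and per-file checksums of one pipeline run."""

    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = "0.1.0"
    outputs: dict = field(default_factory=dict)

    def record(self, label: str, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[label] = {"path": str(path), "sha256": digest}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "inputs": self.inputs,
                    "params": self.params,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
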