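"""Readers and writers for the standard formats the pipeline consumes.

Trees are Newick (dendropy containers), sequences are FASTA (Biopython),
and tabular data are CSV/TSV held in label-addressed pandas DataFrames.
All text is UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import csv
import io as _io
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input text (unbalanced tree, headerless FASTA, ragged CSV...)."""


# ---------------------------------------------------------------------------
# Newick


def parse_newick(text: str, missing_length: str = "reject") -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree.

    Branch lengths are required by default because every downstream distance
    is meaningless without them; ``missing_length="zero"`` imputes 0 instead.
    Quoted labels and square-bracket comments are accepted (comments are
    stripped); internal node labels are preserved but unused downstream.
    """
    if missing_length not in ("reject", "zero"):
        raise ValueError("missing_length must be 'reject' or 'zero'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge carries no length in most dialects
        if edge.length is None:
            if missing_length == "reject":
                node = edge.head_node
                name = node.taxon.label if node.taxon else "<internal>"
                raise FormatError(f"missing branch length on edge to {name!r}")
            edge.length = 0.0
        elif edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into an ordered list of (id, sequence) pairs."""
    stripped = text.strip()
    if not stripped:
        raise FormatError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FormatError("FASTA records must start with '>'")
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sequence ids")
    return records


def write_fasta(records: list[tuple[str, str]], width: int = 60) -> str:
    out = _io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in records],
        out,
        "fasta",
    )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Tables


def read_table(source: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a labelled matrix (first row = columns, first column = rows).

    Missing cells become NaN — flagged, never silently zeroed.  Ragged rows
    raise :class:`FormatError` naming the offending line.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = source
    rows = list(csv.reader(_io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r]
    if not rows:
        raise FormatError("empty table")
    width = len(rows[0])
    for row in rows[1:]:
        if len(row) != width:
            raise FormatError(
                f"ragged table: row {row[0]!r} has {len(row)} fields, expected {width}"
            )
    try:
        df = pd.read_csv(_io.StringIO(text), sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged table: {exc}") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("duplicate row or column labels")
    return df


def write_table(df: pd.DataFrame, path: str | Path | None = None, delimiter: str = ",") -> str:
    text = df.to_csv(sep=delimiter)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Run configuration

_THRESHOLD_RANGES = {
    "identity": (0.0, 1.0),
    "max_gap_prop": (0.0, 1.0),
    "min_ref_fraction": (0.0, 1.0),
    "dbscan_eps": (0.0, float("inf")),
    "alpha": (0.0, 1.0),
}

_DEFAULT_THRESHOLDS = {
    "identity": 0.99,
    "max_gap_prop": 0.8,
    "min_ref_fraction": 0.5,
    "dbscan_eps": 0.03,
    "alpha": 0.05,
}


@dataclass
class RunConfig:
    """Seed plus the named thresholds every stage reads.

    Defaults are the study conditions: 99% dereplication identity, 0.8 gap
    proportion, 50% reference occupancy, DBSCAN radius 0.03, alpha 0.05.
    """

    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    outdir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        merged = dict(_DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for name, value in self.thresholds.items():
            lo, hi = _THRESHOLD_RANGES.get(name, (-float("inf"), float("inf")))
            if not (lo <= value <= hi):
                raise ValueError(f"threshold {name}={value} outside [{lo}, {hi}]")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        return cls(
            seed=data.get("seed", 0),
            thresholds=data.get("thresholds", {}),
            outdir=Path(data.get("outdir", ".")),
        )
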