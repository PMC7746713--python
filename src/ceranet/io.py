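"""Domain containers and readers/writers for the standard formats the pipeline touches.

Tabular data travels as TSV (tab-delimited, '.' decimal, UTF-8, ``#`` comment
lines ignored); sequences as FASTA; gene sets as GMT.  circRNAs are keyed by
whatever identifier the user supplies (accession or a "chr:start-end" string);
coordinates are never parsed -- no computation here needs genomic position.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionPanel",
    "InteractionTable",
    "GeneSetCollection",
    "SequenceSet",
    "CeranetIOError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_table_tsv",
    "write_table_tsv",
]

FEATURE_CLASSES = ("circRNA", "miRNA", "gene")

_RNA_ALPHABET = frozenset("ACGU")


class CeranetIOError(ValueError):
    """Malformed input; message locates the offending record."""


@dataclass
class ExpressionPanel:
    """Feature x tissue matrix of non-negative normalized expression.

    ``values`` is a DataFrame indexed by feature id with tissue ids as
    columns.  One feature class (circRNA, miRNA or gene) per panel; the unit
    is CPM for miRNAs/genes and SRPBM for circRNAs.
    """

    values: pd.DataFrame
    feature_class: str
    unit_label: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CeranetIOError(f"duplicate feature id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise CeranetIOError(f"duplicate tissue id: {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InteractionTable:
    """Typed edges (circ-mir or mir-gene) with per-criterion scores.

    ``edges`` columns: source_id, target_id, one column per criterion
    (non-negative), plus optional front_index / pareto_score once ranked.
    """

    edges: pd.DataFrame
    edge_type: str  # "circ-mir" or "mir-gene"

    RESERVED = ("source_id", "target_id", "front_index", "pareto_score")

    def __post_init__(self) -> None:
        if self.edge_type not in ("circ-mir", "mir-gene"):
            raise ValueError(f"edge_type must be 'circ-mir' or 'mir-gene', got {self.edge_type!r}")
        for col in ("source_id", "target_id"):
            if col not in self.edges.columns:
                raise ValueError(f"edges must carry a {col!r} column")
        pairs = self.edges[["source_id", "target_id"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate edge: ({dup.source_id!r}, {dup.target_id!r})")
        for c in self.criteria:
            col = self.edges[c].to_numpy(dtype=float)
            if (col < 0).any():
                raise ValueError(f"criterion {c!r} contains negative values")
        if "pareto_score" in self.edges.columns:
            s = self.edges["pareto_score"].dropna()
            if ((s < 0) | (s > 1)).any():
                raise ValueError("pareto_score must lie in [0, 1]")

    @property
    def criteria(self) -> list[str]:
        return [c for c in self.edges.columns if c not in self.RESERVED]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class SequenceSet:
    """RNA sequences keyed by id; T is normalized to U at construction."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for rid, seq in self.records.items():
            s = seq.upper().replace("T", "U")
            if not s:
                raise CeranetIOError(f"empty sequence for record {rid!r}")
            bad = set(s) - _RNA_ALPHABET
            if bad:
                raise CeranetIOError(
                    f"illegal character(s) {sorted(bad)} in sequence {rid!r}"
                )
            clean[rid] = s
        self.records = clean

    def __getitem__(self, rid: str) -> str:
        return self.records[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.records

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.records.items()}


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CeranetIOError(f"{path}: empty table") from exc


def read_expression_tsv(path, feature_class: str, unit_label: str = "") -> ExpressionPanel:
    """Read a feature x tissue TSV (header = tissue ids, first column = feature id)."""
    raw = _read_tsv(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise CeranetIOError(f"{path}: duplicate feature id {dup!r}")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        cells = raw[col].to_numpy()
        parsed = np.empty(len(cells), dtype=float)
        for i, cell in enumerate(cells):
            try:
                parsed[i] = float(cell)  # exact strtod; bit-faithful round-trips
            except (TypeError, ValueError):
                raise CeranetIOError(
                    f"{path}: non-numeric or missing cell at row {raw.index[i]!r}, "
                    f"column {col!r}"
                ) from None
        if np.isnan(parsed).any():
            row = raw.index[int(np.where(np.isnan(parsed))[0][0])]
            raise CeranetIOError(
                f"{path}: non-numeric or missing cell at row {row!r}, column {col!r}"
            )
        values[col] = parsed
    return ExpressionPanel(values=values, feature_class=feature_class, unit_label=unit_label)


def write_expression_tsv(panel: ExpressionPanel, path, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        buf = _io.StringIO()
        panel.values.to_csv(buf, sep="\t", index_label="feature_id", float_format="%.17g")
        fh.write(buf.getvalue())


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT: ``name <tab> description <tab> gene...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CeranetIOError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise CeranetIOError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise CeranetIOError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (desc, frozenset(genes))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_fasta(path) -> SequenceSet:
    """Read FASTA; ids are the first whitespace token of the header, T -> U."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise CeranetIOError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in seqs.records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table_tsv(path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a generic tidy TSV (comment lines ignored), checking required columns."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise CeranetIOError(f"{path}: empty table") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise CeranetIOError(f"{path}: missing required column(s) {missing}")
    return df


def write_table_tsv(df: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        buf = _io.StringIO()
        df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
        fh.write(buf.getvalue())
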