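"""Readers and writers for the pipeline's file formats.

Aligned FASTA (Biopython), Newick with bootstrap supports as internal node
labels (dendropy), and the CSV schemas for isolate observations, count
tables and long-format trait tables. Parsers are strict: malformed input
fails with the offending record named, and every writer/reader pair
round-trips its in-memory object exactly.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylogeny import Alignment

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "read_observations",
    "write_observations",
    "read_counts",
    "write_counts",
    "read_trait_table",
    "write_trait_table",
]

OBSERVATION_COLUMNS = [
    "isolate_id",
    "source",
    "variety",
    "treatment",
    "experiment",
    "eric_bands",
    "box_bands",
]


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; unequal row lengths name the record."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in taxa:
            raise ValueError(f"{path}: duplicate taxon label {rec.id!r}")
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise ValueError(f"{path}: no FASTA records found")
    length = len(rows[0])
    for label, row in zip(taxa, rows):
        if len(row) != length:
            raise ValueError(
                f"{path}: record {label!r} has length {len(row)}, expected {length}"
            )
    return Alignment(taxa=taxa, rows=rows)


def write_alignment(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(alignment.taxa, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tree(tree: dendropy.Tree, path) -> None:
    """Write Newick; internal node labels carry bootstrap supports."""
    for nd in tree.preorder_node_iter():
        support = getattr(nd, "support", None)
        if support is not None and not nd.is_leaf():
            nd.label = f"{support:g}"
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


def read_tree(path) -> dendropy.Tree:
    """Read Newick; numeric internal node labels become ``node.support``."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            try:
                nd.support = float(nd.label)
            except ValueError:
                pass
    return tree


def _join_bands(bands) -> str:
    return ";".join(str(int(b)) for b in bands)


def _split_bands(text, where: str) -> list[int]:
    if pd.isna(text) or text == "":
        return []
    try:
        return [int(tok) for tok in str(text).split(";")]
    except ValueError as err:
        raise ValueError(f"{where}: malformed band list {text!r}") from err


def write_observations(observations: pd.DataFrame, path) -> None:
    out = observations.copy()
    for col in ("eric_bands", "box_bands"):
        if col in out.columns:
            out[col] = out[col].map(_join_bands)
    out.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"isolate_id": str})
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: observation table lacks columns {missing}")
    for col in ("eric_bands", "box_bands"):
        df[col] = [
            _split_bands(v, f"{path} line {i + 2}") for i, v in enumerate(df[col])
        ]
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=True)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="experiment")
    if df.isna().any().any():
        raise ValueError(f"{path}: count table contains missing cells")
    return df.astype(int)


TRAIT_COLUMNS = ["variety", "treatment", "block", "experiment", "trait", "value"]


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trait_table(path, require_balanced: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trait table lacks columns {missing}")
    if df["value"].isna().any():
        bad = df.index[df["value"].isna()][0]
        raise ValueError(f"{path}: missing value at row {bad + 2}")
    if require_balanced:
        for trait, sub in df.groupby("trait"):
            sizes = sub.groupby(["variety", "treatment", "block", "experiment"]).size()
            expected = (
                sub["variety"].nunique()
                * sub["treatment"].nunique()
                * sub["block"].nunique()
                * sub["experiment"].nunique()
            )
            if len(sizes) != expected or sizes.nunique() != 1:
                raise ValueError(
                    f"{path}: trait {trait!r} is not balanced over "
                    "variety x treatment x block x experiment"
                )
    return df
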