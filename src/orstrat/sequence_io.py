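"""Readers and writers for the external formats the pipeline touches.

Downstream modules never parse files themselves: they consume the domain
types defined here (:class:`SeqRecord`, :class:`GeneModel`,
:class:`CountMatrix`) or in sibling modules (``HitRecord``/``HitTable`` in
:mod:`orstrat.similarity`).

Coordinate convention: GFF3 coordinates are 1-based inclusive and are kept
in those units everywhere — no half-open conversion is ever applied.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("orstrat")

#: The 20 canonical amino-acid letters plus X (unknown residue, present in
#: GenBank proteomes).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Gene categories used throughout: nine-exon odorant receptors, other
#: odorant receptors, and everything else.
CATEGORIES = ("nine_exon_or", "other_or", "non_or")

BLAST_TAB_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence: identifier token, free-text description, residues.

    Residues are uppercase and restricted to the 20 canonical amino-acid
    letters plus ``X``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residue letters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene feature: scaffold interval (1-based inclusive), strand, category."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    category: str = "non_or"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class CountMatrix:
    """Raw (un-normalized) transcript counts: genes x samples plus a
    sample -> tissue map.

    Counts may be fractional (pseudo-alignment emits fractional estimated
    counts) and are stored as non-negative reals without rounding.
    """

    def __init__(self, counts: pd.DataFrame, tissue_of: Mapping[str, str]):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = counts.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in tissue_of]
        if missing:
            raise ValueError(f"samples without a tissue label: {missing}")
        self.counts = counts.astype(float)
        self.tissue_of = {s: tissue_of[s] for s in counts.columns}

    # -- introspection ------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.sample_ids if self.tissue_of[s] == tissue]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.tissue_of)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.tissue_of == other.tissue_of

    def __repr__(self) -> str:
        return (
            f"CountMatrix({len(self.gene_ids)} genes x {len(self.sample_ids)} "
            f"samples, tissues={self.tissues})"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a protein FASTA into :class:`SeqRecord` objects.

    Residues are concatenated across wrapped lines and uppercased. Raises on
    an empty file and on duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | os.PathLike,
    category_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Only features of type ``gene`` are returned; each must carry an ``ID``
    attribute. Genes absent from *category_map* get category ``non_or``.
    Strand ``.`` is rejected: tandem-array detection requires orientation.
    """
    category_map = dict(category_map or {})
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="error", keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise FormatError(f"duplicate gene id {gid!r} in {path}")
        seen.add(gid)
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"gene {gid!r}: strand {feat.strand!r} not allowed "
                "(orientation required for array detection)"
            )
        if feat.start > feat.end:
            raise FormatError(f"gene {gid!r}: start {feat.start} > end {feat.end}")
        genes.append(GeneModel(
            gene_id=gid, scaffold=feat.seqid,
            start=int(feat.start), end=int(feat.end),
            strand=feat.strand,
            category=category_map.get(gid, "non_or"),
        ))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike,
               source: str = "orstrat") -> None:
    """Write gene features as GFF3; coordinates pass through untouched."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (12-column "outfmt 6")
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | os.PathLike, species_of: Mapping[str, str]):
    """Read a 12-column BLAST tabular file into a :class:`~orstrat.similarity.HitTable`.

    Subject species are resolved through *species_of*; an unknown subject id
    is an error naming the id.
    """
    from .similarity import HitRecord, HitTable  # local import avoids a cycle

    try:
        df = pd.read_csv(
            str(path), sep="\t", header=None, names=BLAST_TAB_COLUMNS,
            dtype={"qseqid": str, "sseqid": str}, comment="#",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return HitTable(records=[])
    if df.empty:
        return HitTable(records=[])
    if df.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 tab-separated columns")
    for col in ("evalue", "bitscore", "pident"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric values in column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        if row.sseqid not in species_of:
            raise FormatError(f"subject id {row.sseqid!r} missing from species map")
        records.append(HitRecord(
            query_id=row.qseqid, subject_id=row.sseqid,
            subject_species=species_of[row.sseqid],
            evalue=float(row.evalue), bitscore=float(row.bitscore),
            pident=float(row.pident),
        ))
    return HitTable(records=records)


def write_blast_tab(hits, path: str | os.PathLike) -> None:
    """Serialize a HitTable back to the 12-column dialect.

    Fields the in-memory model does not track (alignment coordinates,
    mismatch/gap counts) are written as their neutral placeholders.
    """
    with open(path, "w") as fh:
        for r in hits.records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pident:.1f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts_matrix(path: str | os.PathLike, tissue_of: Mapping[str, str]) -> CountMatrix:
    """Read one TSV with a ``gene_id`` column plus one column per sample."""
    df = pd.read_csv(str(path), sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing 'gene_id' header column")
    df = df.set_index("gene_id")
    return CountMatrix(df, tissue_of)


def read_counts_per_sample(
    paths: Mapping[str, str | os.PathLike], tissue_of: Mapping[str, str],
) -> CountMatrix:
    """Assemble a CountMatrix from per-sample two-column (target_id, est_count)
    TSVs, one file per sample.

    Gene sets may differ between files; the union is taken and missing
    entries filled with 0 (logged as a warning).
    """
    columns: dict[str, pd.Series] = {}
    for sample, p in paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"count file for sample {sample!r} missing: {p}")
        df = pd.read_csv(str(p), sep="\t")
        if not {"target_id", "est_count"} <= set(df.columns):
            raise FormatError(f"{p}: expected columns target_id, est_count")
        columns[sample] = df.set_index("target_id")["est_count"].astype(float)
    mat = pd.DataFrame(columns)
    if mat.isna().any().any():
        logger.warning(
            "per-sample count files have disjoint gene sets; missing entries set to 0"
        )
        mat = mat.fillna(0.0)
    mat.index.name = "gene_id"
    return CountMatrix(mat, tissue_of)


def write_counts_matrix(cm: CountMatrix, path: str | os.PathLike) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(str(path), sep="\t")


def read_category_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (gene_id, category) into a dict."""
    df = pd.read_csv(str(path), sep="\t", header=None, names=["gene_id", "category"],
                     dtype=str, comment="#")
    bad = sorted(set(df["category"]) - set(CATEGORIES))
    if bad:
        raise FormatError(f"{path}: unknown categories {bad}")
    return dict(zip(df["gene_id"], df["category"]))


def write_category_map(categories: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gid, cat in categories.items():
            fh.write(f"{gid}\t{cat}\n")
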