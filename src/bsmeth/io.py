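"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive (GFF3 / Bismark convention).
* BED is 0-based half-open on disk and converted on read/write.
* The cytosine report is the Bismark-style 7-column TSV:
  chrom, pos (1-based), strand, count_meth, count_unmeth, context,
  trinucleotide (on the cytosine's strand).
* All writers emit a deterministic ordering: chromosomes in genome order
  (or lexicographic when no genome is given), then position, then strand.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    CONTEXTS,
    DEFAULT_TE_CLASSES,
    RECORD_COLUMNS,
    FormatError,
    GeneModel,
    GenomeSequence,
    TEAnnotation,
    ValidationError,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, spike_in_chrom: str | None = None) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; duplicate headers are rejected; characters
    outside {A, C, G, T, N} raise :class:`FormatError`.
    """
    path = Path(path)
    chroms: dict[str, str] = {}
    n_records = 0
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header, got {first[:40]!r}")
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        if record.id in chroms:
            raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
        chroms[record.id] = str(record.seq).upper()
    if n_records == 0:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeSequence(chroms=chroms, spike_in_chrom=spike_in_chrom)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name in genome.names:
            out.write(f">{name}\n")
            seq = genome.chroms[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cytosine report


def _validate_context(df: pd.DataFrame, path: str | Path) -> None:
    """Check the context column against the trinucleotide column."""
    tri = df["trinucleotide"].astype(str)
    b2 = tri.str[1]
    b3 = tri.str[2]
    is_h2 = b2.isin(list("ACT"))
    is_h3 = b3.isin(list("ACT"))
    expected = np.select(
        [b2 == "G", is_h2 & (b3 == "G"), is_h2 & is_h3],
        ["CG", "CHG", "CHH"],
        default="?",
    )
    bad = (df["context"].to_numpy() != expected) | (tri.str.len() != 3).to_numpy()
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise ValidationError(
            f"{path}: line {i + 1}: context {df['context'].iat[i]!r} inconsistent "
            f"with trinucleotide {tri.iat[i]!r}"
        )


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-style 7-column cytosine report into a record table.

    Returns an empty table with the canonical columns for an empty file.
    Row order is preserved.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=RECORD_COLUMNS,
            header=None,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "count_meth": np.int64,
                "count_unmeth": np.int64,
                "context": str,
                "trinucleotide": str,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            RECORD_COLUMNS, [str, np.int64, str, np.int64, np.int64, str, str])})
    if len(df) == 0:
        return df
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        i = int(((df["count_meth"] < 0) | (df["count_unmeth"] < 0)).idxmax())
        raise ValidationError(f"{path}: line {i + 1}: negative read count")
    if not df["strand"].isin(["+", "-"]).all():
        i = int((~df["strand"].isin(["+", "-"])).idxmax())
        raise ValidationError(f"{path}: line {i + 1}: bad strand {df['strand'].iat[i]!r}")
    if not df["context"].isin(CONTEXTS).all():
        i = int((~df["context"].isin(CONTEXTS)).idxmax())
        raise ValidationError(f"{path}: line {i + 1}: unknown context {df['context'].iat[i]!r}")
    _validate_context(df, path)
    return df


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as a 7-column cytosine report (lossless round-trip)."""
    records[RECORD_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED)


def _gene_from_gff(db: gffutils.FeatureDB, gene) -> GeneModel:
    def spans(ftype: str) -> list[tuple[int, int]]:
        return sorted((f.start, f.end) for f in db.children(gene, featuretype=ftype))

    exons = spans("exon")
    for start, end in exons:
        if start < gene.start or end > gene.end:
            raise ValidationError(
                f"gene {gene.id}: exon {start}-{end} outside gene span "
                f"{gene.start}-{gene.end}"
            )
    return GeneModel(
        gene_id=gene.id,
        chrom=gene.seqid,
        strand=gene.strand if gene.strand in "+-" else "+",
        transcript_start=gene.start,
        transcript_end=gene.end,
        exons=exons,
        cds=spans("CDS"),
        utr5=spans("five_prime_UTR"),
        utr3=spans("three_prime_UTR"),
    )


def _read_gff3_genes(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return [_gene_from_gff(db, g) for g in db.features_of_type("gene", order_by=("seqid", "start"))]


def _read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start0", 2: "end0"})
    if (df["end0"] <= df["start0"]).any():
        raise ValidationError(f"{path}: BED interval with end <= start")
    # BED 0-based half-open -> 1-based inclusive
    df["start"] = df["start0"] + 1
    df["end"] = df["end0"]
    return df


def read_annotations(path: str | Path, kind: str) -> list[GeneModel] | list[TEAnnotation]:
    """Read gene or TE annotations from GFF3 or BED.

    ``kind`` is ``"gene"`` or ``"te"``. Internal coordinates are uniformly
    1-based inclusive regardless of the on-disk format. For TEs read from
    BED, the class is taken from column 7 when present; unknown classes map
    to ``"other"`` with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if kind == "gene":
        if suffix in (".gff", ".gff3"):
            return _read_gff3_genes(path)
        if suffix == ".bed":
            df = _read_bed(path)
            return [
                GeneModel(
                    gene_id=str(row.get(3, f"gene{i}")),
                    chrom=str(row["chrom"]),
                    strand=str(row.get(5, "+")),
                    transcript_start=int(row["start"]),
                    transcript_end=int(row["end"]),
                )
                for i, row in df.iterrows()
            ]
        raise FormatError(f"{path}: unrecognized annotation format {suffix!r}")
    if kind == "te":
        if suffix == ".bed":
            df = _read_bed(path)
            tes = []
            warned: set[str] = set()
            for i, row in df.iterrows():
                te_class = str(row.get(6, "other"))
                if te_class not in DEFAULT_TE_CLASSES:
                    if te_class not in warned:
                        warnings.warn(
                            f"unknown TE class {te_class!r} mapped to 'other'",
                            stacklevel=2,
                        )
                        warned.add(te_class)
                    te_class = "other"
                tes.append(
                    TEAnnotation(
                        te_id=str(row.get(3, f"te{i}")),
                        chrom=str(row["chrom"]),
                        strand=str(row.get(5, "+")),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        te_class=te_class,
                    )
                )
            return tes
        raise FormatError(f"{path}: TEs are read from BED; got {suffix!r}")
    raise ValueError(f"kind must be 'gene' or 'te', got {kind!r}")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/UTR/CDS hierarchy)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tbsmeth\t"
            tail = f"\t.\t{g.strand}\t."
            out.write(
                f"{base}gene\t{g.transcript_start}\t{g.transcript_end}{tail}\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            out.write(
                f"{base}mRNA\t{g.transcript_start}\t{g.transcript_end}{tail}\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds),
                ("three_prime_UTR", g.utr3),
            ):
                for j, (start, end) in enumerate(ivs, 1):
                    out.write(
                        f"{base}{ftype}\t{start}\t{end}{tail}\t"
                        f"ID={mrna}.{ftype}{j};Parent={mrna}\n"
                    )


def write_te_bed(tes: list[TEAnnotation], path: str | Path) -> None:
    """Write TEs as BED6+1 (column 7 = TE class), 0-based half-open."""
    with open(path, "w") as out:
        for te in tes:
            out.write(
                f"{te.chrom}\t{te.start - 1}\t{te.end}\t{te.te_id}\t0\t"
                f"{te.strand}\t{te.te_class}\n"
            )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a table with 1-based inclusive ``start``/``end`` as BED.

    Extra columns ``name``, ``score`` and ``strand`` are used when present.
    """
    cols = intervals.columns
    with open(path, "w") as out:
        for row in intervals.itertuples(index=False):
            d = row._asdict()
            fields = [str(d["chrom"]), str(int(d["start"]) - 1), str(int(d["end"]))]
            if "name" in cols:
                fields.append(str(d["name"]))
                fields.append(str(d.get("score", 0)))
                fields.append(str(d.get("strand", ".")))
            out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV.

    Two dialects are accepted: headerless ``gene_id<TAB>fpkm[<TAB>de_label]``
    and a headered table whose first column is ``gene_id`` (which may carry
    per-condition columns ``fpkm_control``/``fpkm_case``).
    """
    with open(path) as handle:
        first = handle.readline()
    has_header = first.split("\t")[0].strip() == "gene_id"
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        ncols = len(first.rstrip("\n").split("\t")) if first.strip() else 2
        names = ["gene_id", "fpkm", "de_label"][:ncols]
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    if "de_label" in df.columns:
        df["de_label"] = df["de_label"].fillna("none")
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm")]
    for c in fpkm_cols:
        if (df[c] < 0).any():
            raise ValidationError(f"{path}: negative FPKM in column {c!r}")
    return df


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False, float_format="%.6g")
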