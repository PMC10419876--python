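"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are converted at the file boundary only:
GFF3 and the cytosine report are 1-based inclusive on disk, BED is 0-based
half-open; everything is 0-based half-open in memory.

The per-cytosine count table uses the Bismark CX-report dialect: seven
tab-separated columns ``chrom, pos(1-based), strand, count_methylated,
count_unmethylated, context, trinucleotide``, sorted by (chrom, pos).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CX_COLUMNS = ["chrom", "pos", "strand", "m", "u", "context", "trinucleotide"]
_CONTEXT_TOKENS = {"CG", "CHG", "CHH"}


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: pd.DataFrame, subfeatures: pd.DataFrame, path: str | Path) -> None:
    """Gene models to GFF3 (1-based inclusive); subfeatures carry Parent."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.sort_values(["chrom", "start"]).itertuples(index=False):
            fh.write(
                f"{g.chrom}\tmethylink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id}\n"
            )
            sub = subfeatures[subfeatures["gene_id"] == g.gene_id]
            for f in sub.sort_values("start").itertuples(index=False):
                fh.write(
                    f"{f.chrom}\tmethylink\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t."
                    f"\tParent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GFF3 -> (genes, subfeatures) with internal 0-based half-open coords."""
    genes, subfeats = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated GFF3 fields, got {len(fields)}"
                )
            chrom, _source, kind, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 0 or end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end}]")
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if kind == "gene":
                if "ID" not in attr_map:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                genes.append(
                    {"gene_id": attr_map["ID"], "chrom": chrom, "start": start_i,
                     "end": end_i, "strand": strand}
                )
            else:
                if "Parent" not in attr_map:
                    raise ValueError(f"{path}:{lineno}: subfeature without Parent attribute")
                subfeats.append(
                    {"gene_id": attr_map["Parent"], "chrom": chrom, "kind": kind,
                     "start": start_i, "end": end_i, "strand": strand}
                )
    return (
        pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        pd.DataFrame(subfeats, columns=["gene_id", "chrom", "kind", "start", "end", "strand"]),
    )


# ---------------------------------------------------------------- BED

def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """BED6 (0-based half-open).  Optional columns name/score/strand default
    to ``.``/0/``.``."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "name", ".")
            score = getattr(row, "score", 0)
            strand = getattr(row, "strand", ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval")
            rows.append(
                {
                    "chrom": fields[0], "start": start, "end": end,
                    "name": fields[3] if len(fields) > 3 else ".",
                    "score": int(fields[4]) if len(fields) > 4 else 0,
                    "strand": fields[5] if len(fields) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMR table -> BED6 rows: name = context:direction, score = 1000|delta|."""
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["context"] + ":" + dmrs["direction"],
            "score": (1000 * dmrs["delta"].abs()).round().astype(int),
            "strand": ".",
        }
    )


# ---------------------------------------------------------------- CX report

def write_cx(counts: pd.DataFrame, path: str | Path) -> None:
    """One sample's per-cytosine counts to the CX dialect (1-based)."""
    out = counts[["chrom", "pos", "strand", "m", "u", "context", "trinucleotide"]].copy()
    out["pos"] = out["pos"] + 1
    out = out.sort_values(["chrom", "pos"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cx(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """CX dialect -> internal 0-based table; validates tokens and counts."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed cytosine report: {exc}") from exc
    if df.empty:
        return df
    for col in ("pos", "m", "u"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 1 if len(bad) else "?"
            raise ValueError(f"{path}:{line}: non-integer value in column {col!r}")
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise ValueError(f"{path}:{line}: position must be >= 1")
    if (df["m"] < 0).any() or (df["u"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    bad_ctx = ~df["context"].isin(_CONTEXT_TOKENS)
    if bad_ctx.any():
        line = int(df.index[bad_ctx][0]) + 1
        raise ValueError(
            f"{path}:{line}: unknown context token {df.loc[bad_ctx, 'context'].iloc[0]!r}"
        )
    df["pos"] = df["pos"] - 1
    if chrom_lengths is not None:
        for chrom, sub in df.groupby("chrom"):
            if chrom not in chrom_lengths:
                raise ValueError(f"{path}: unknown contig {chrom!r}")
            if (sub["pos"] >= chrom_lengths[chrom]).any():
                raise ValueError(f"{path}: coordinate beyond end of contig {chrom!r}")
    return df


# ---------------------------------------------------------------- TSV tables

def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_counts_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
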