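"""Readers and writers for the plain-text formats the pipeline touches:
BED3/6 and BED12, FASTA, TSV fold-change tables, YAML configs and JSON
summaries.

BED files are parsed by hand on purpose: records are 3-6 columns, the
formats carry no escaping, and parse errors must name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .types import FoldChangeTable, GeneModel, GenomicInterval


class BedParseError(ValueError):
    pass


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into a list of intervals.

    Input order is preserved; name/score/strand are populated when present.
    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, score=score, name=name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals, path) -> None:
    """Write intervals as BED, emitting only as many columns as populated.

    Round-trips with :func:`read_bed` on the populated fields.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_strand = iv.strand != "."
            if iv.name is not None or iv.score is not None or has_strand:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or has_strand:
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
            if has_strand:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_foldchange_table(path) -> FoldChangeTable:
    """Read a TSV with a header of experiment ids and gene ids in column 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.isna()
    if bad.to_numpy().any():
        i, j = list(zip(*bad.to_numpy().nonzero()))[0]
        raise ValueError(
            f"{path}: missing/non-numeric value at gene {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric column {col!r}")
    return FoldChangeTable(df)


def write_foldchange_table(table: FoldChangeTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="gene_id")


# --- FASTA -----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- Gene models -----------------------------------------------------------

def read_bed12(path) -> list[GeneModel]:
    """Read gene models from BED12 (exon blocks -> exons; introns derived)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + L) for s, L in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def read_gtf_exons(path) -> list[GeneModel]:
    """Read a minimal GTF dialect: exon lines only, gene_id attribute required.

    Gene span is the hull of its exons; GTF coordinates are 1-based inclusive.
    """
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError("GTF exon line lacks gene_id attribute")
            rec = by_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append((start1 - 1, end1))
    genes = []
    for gid, rec in by_gene.items():
        exons = sorted(rec["exons"])
        genes.append(GeneModel(gid, rec["chrom"], rec["strand"],
                               exons[0][0], exons[-1][1], exons))
    return genes


def write_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.gene_start, g.gene_end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - g.gene_start) for s, e in exons)
            fh.write("\t".join([
                g.chrom, str(g.gene_start), str(g.gene_end), g.gene_id, "0",
                g.strand, str(g.gene_start), str(g.gene_end), "0",
                str(len(exons)), sizes, starts,
            ]) + "\n")


# --- Config / summaries ----------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_json_summary(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
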