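"""File-format helpers shared by every pipeline stage.

Counts and tables travel as TSV, annotation as GTF (1-based, closed
intervals, ``gene_id``/``transcript_id``/``biotype`` attributes), sequences
as FASTA over the RNA alphabet, gene sets as GMT, networks as SIF, and run
manifests as YAML.  Genomic coordinates are 1-based closed everywhere inside
the package; conversion to other dialects happens here, once.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "biotype"]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    """Write a features x samples count matrix with a ``feature_id`` column."""
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_table(df: pd.DataFrame, path, header_comments: dict | None = None) -> None:
    """Write a TSV table, optionally preceded by ``# key: value`` comment lines."""
    buf = _io.StringIO()
    for key, val in (header_comments or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gtf(features: pd.DataFrame, path, source: str = "cernet") -> None:
    """Write a feature table (1-based closed intervals) as GTF transcript lines."""
    lines = []
    for row in features.itertuples(index=False):
        attrs = (
            f'gene_id "{row.feature_id}"; transcript_id "{row.feature_id}"; '
            f'biotype "{row.biotype}";'
        )
        lines.append(
            f"{row.chrom}\t{source}\ttranscript\t{row.start}\t{row.end}"
            f"\t.\t{row.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path) -> pd.DataFrame:
    """Read GTF into the package feature-table layout (1-based closed)."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    out = pd.DataFrame(
        {
            "feature_id": df["transcript_id"],
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"] + 1,  # pyranges is 0-based half-open
            "end": df["End"],
            "strand": df["Strand"].astype(str),
            "biotype": df.get("biotype", pd.Series(["."] * len(df))),
        }
    )
    return out.reset_index(drop=True)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, rna: bool = True) -> dict[str, str]:
    """Read FASTA into an id -> sequence dict; DNA input is converted to RNA."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if rna:
            s = s.replace("T", "U")
        seqs[rec.id] = s
    return seqs


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then member ids."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = ".") -> None:
    lines = [
        "\t".join([name, description] + sorted(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_sif(edges: pd.DataFrame, path, source_col: str, target_col: str,
              relation: str = "interacts") -> None:
    """Simple interaction format: ``source relation target`` per line."""
    lines = [
        f"{row[source_col]}\t{relation}\t{row[target_col]}"
        for _, row in edges.iterrows()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
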