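"""Table schemas and readers/writers for pipeline artifacts.

All genomic intervals are 0-based half-open internally.  BED exports keep
that convention (it is the BED convention); conversion to 1-based happens
only in explicitly labeled export helpers (GFF3).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

#: Column dictionaries for every TSV artifact the pipeline reads or writes.
SCHEMAS: dict[str, list[str]] = {
    "discordant_pairs": [
        "sample", "chrom1", "start1", "end1", "strand1", "mapq1", "family1",
        "chrom2", "start2", "end2", "strand2", "mapq2", "family2",
    ],
    "split_reads": ["sample", "chrom", "pos", "strand", "seq", "ref_context"],
    "panel_calls": ["sample", "chrom", "pos", "family"],
    "sv_calls": [
        "sample", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b",
        "support", "mapq", "length",
    ],
    "candidates": [
        "sample", "chrom", "window_start", "window_end", "family",
        "pos_support", "neg_support", "somatic",
    ],
    "transductions": [
        "sample", "chrom", "pos", "source_id", "cytoband", "tclass",
        "support", "ambiguous_source",
    ],
    "insertions": [
        "sample", "chrom", "window_start", "window_end", "midpoint", "family",
        "method", "poly_tail", "strand", "gene_ids", "nearest_gene",
        "region_class", "orientation", "replication_bin", "chromatin",
        "source_id",
    ],
    "truth": [
        "sample", "chrom", "pos", "family", "somatic", "transduction",
        "source_id", "gene_id", "poly_tail", "strand", "sub_threshold",
    ],
    "clinical": [
        "sample", "insertion_count", "msi", "cimp", "ai_fraction", "tp53",
        "braf", "kras", "dukes_stage", "age", "sex", "location",
        "mean_coverage", "followup_days", "event",
    ],
    "methylation": ["probe_id", "gene", "sample", "ratio", "is_normal"],
    "ai_events": ["sample", "chrom", "start", "end"],
    "l1hs_catalog": [
        "element_id", "cytoband", "chrom", "start", "end", "strand",
        "three_prime_end", "germline_active", "cancer_active",
    ],
    "genes": ["gene_id", "name", "chrom", "start", "end", "strand", "coding",
              "fragile"],
    "exons": ["gene_id", "transcript_id", "chrom", "start", "end"],
    "track": ["chrom", "start", "end", "label"],
    "variants": ["sample", "gene", "codon", "consequence", "protein_change",
                 "coverage", "allelic_fraction", "quality"],
}


class SchemaError(ValueError):
    """Raised when a file does not match its declared schema."""


def write_table(df: pd.DataFrame, path: str | Path, schema_id: str) -> None:
    cols = SCHEMAS[schema_id]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema_id}: missing columns {missing}")
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    cols = SCHEMAS[schema_id]
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != cols:
        raise SchemaError(
            f"{schema_id}: malformed header at line 1 of {path}: "
            f"expected {cols}, found {header}"
        )
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              chrom="chrom", start="start", end="end",
              name=None, score=None) -> None:
    """Write intervals as BED (0-based half-open, like the internal model)."""
    out = pd.DataFrame({
        0: df[chrom], 1: df[start].astype(int), 2: df[end].astype(int),
    })
    out[3] = df[name].astype(str) if name else "."
    out[4] = df[score] if score is not None else 0
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "name"})
    if df.shape[1] > 4:
        df = df.rename(columns={4: "score"})
    return df


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame,
               path: str | Path) -> None:
    """Export gene models as GFF3 (1-based inclusive, per the format)."""
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    ex_by_gene = dict(tuple(exons.groupby("gene_id", sort=False)))
    for g in genes.itertuples():
        attrs = f"ID={g.gene_id};Name={g.name};biotype=" + (
            "protein_coding" if g.coding else "other")
        buf.write(f"{g.chrom}\tretrocall\tgene\t{g.start + 1}\t{g.end}\t.\t"
                  f"{g.strand}\t.\t{attrs}\n")
        for e in ex_by_gene.get(g.gene_id, pd.DataFrame()).itertuples():
            buf.write(f"{e.chrom}\tretrocall\texon\t{e.start + 1}\t{e.end}\t"
                      f".\t{g.strand}\t.\tParent={e.transcript_id}\n")
    Path(path).write_text(buf.getvalue())


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
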