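"""Readers and writers for the plain-text formats the toolkit consumes:
seed FASTA, probe FASTA, BED intervals, and gene-expression tables."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probe_design import ProbeRecord, SeedSite

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_seed_fasta(path, category_label: str = "canonical") -> list[SeedSite]:
    """Read seed sites from FASTA; record IDs become seed IDs."""
    seeds = [
        SeedSite(
            seed_id=rec.id,
            sequence=str(rec.seq).upper(),
            category_label=category_label,
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seeds:
        raise ValueError(f"no FASTA records found in {path}")
    return seeds


def write_seed_fasta(seeds: Iterable[SeedSite], path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.seed_id, description=s.category_label)
        for s in seeds
    ]
    SeqIO.write(records, str(path), "fasta")


def write_probe_fasta(records: Iterable[ProbeRecord], path) -> None:
    """Write the full probe sequences (scaffold included) as FASTA."""
    out = [
        SeqRecord(Seq(r.full_sequence), id=r.probe_id, description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]] + [
        f"extra{i}" for i in range(max(0, df.shape[1] - len(BED_COLUMNS)))
    ]
    if df.shape[1] < 3:
        raise ValueError(f"{path} is not BED: fewer than 3 columns")
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} intervals with start >= end")
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene-expression table (TSV: gene, chrom, tss, rpkm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss", "rpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"gene table {path} missing columns {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"gene table {path} is empty")
    return df
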