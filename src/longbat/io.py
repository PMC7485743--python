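"""Readers and writers for the pipeline's on-disk formats.

FASTA codon alignments carry ``geneID|species`` headers (two records per
gene); count matrices, sample metadata and annotations are plain TSV;
gene lists are one identifier per line.
"""

from __future__ import annotations

import os
from collections import defaultdict

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .selection import CodonAlignment


def read_codon_alignments(path: str) -> list[CodonAlignment]:
    """Read pairwise codon alignments from a multi-record FASTA.

    Records are grouped by the gene id before the ``|`` separator; each
    gene must have exactly two records, ``geneID|speciesA`` first.
    """
    by_gene: dict[str, list[tuple[str, str]]] = defaultdict(list)
    order: list[str] = []
    for rec in SeqIO.parse(path, "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"FASTA header {rec.id!r} lacks 'gene|species' format")
        gene, species = rec.id.split("|", 1)
        if gene not in by_gene:
            order.append(gene)
        by_gene[gene].append((species, str(rec.seq)))
    alignments = []
    for gene in order:
        recs = by_gene[gene]
        if len(recs) != 2:
            raise ValueError(f"gene {gene}: expected 2 records, found {len(recs)}")
        (sp_a, seq_a), (sp_b, seq_b) = recs
        alignments.append(CodonAlignment(gene, seq_a, seq_b, sp_a, sp_b))
    return alignments


def write_codon_alignments(alignments, path: str) -> None:
    records = []
    for aln in alignments:
        records.append(SeqRecord(Seq(aln.seq_a), id=f"{aln.gene_id}|{aln.species_a}", description=""))
        records.append(SeqRecord(Seq(aln.seq_b), id=f"{aln.gene_id}|{aln.species_b}", description=""))
    SeqIO.write(records, path, "fasta")


def read_counts(path: str) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column = gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.empty:
        raise ValueError(f"{path}: empty count matrix")
    return counts


def read_samples(path: str) -> pd.DataFrame:
    """Sample metadata with columns sample_id, species, sex."""
    samples = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species", "sex"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return samples.set_index("sample_id")


def read_annotation(path: str) -> pd.DataFrame:
    """Gene-to-term annotation with columns gene_id, term_id, term_name."""
    ann = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "term_name" not in ann.columns:
        ann["term_name"] = ann["term_id"]
    return ann


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
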