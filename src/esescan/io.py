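"""Readers and writers for the package's on-disk formats.

FASTA via Biopython; intervals are 0-based half-open in BED; tables are TSV
with headers. The architecture table serializes exon intervals and intron
lengths as ';'-separated fields so a cohort round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqprep import GeneRecord
from .selection import SnpRecord


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_architecture(genes: Sequence[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "transcript_id": g.transcript_id,
            "exon_count": g.exon_count,
            "exon_intervals": ";".join(f"{a}-{b}" for a, b in g.exon_intervals),
            "intron_lengths": ";".join(str(x) for x in g.intron_lengths),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_genes(fasta_path: str | Path, architecture_path: str | Path) -> list[GeneRecord]:
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(architecture_path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in table.iterrows():
        gid = row["gene_id"]
        if gid not in seqs:
            raise ValueError(f"gene {gid!r} in architecture table but not FASTA")
        intervals = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in row["exon_intervals"].split(";")
            if part
        )
        introns = tuple(
            int(x) for x in row["intron_lengths"].split(";") if x
        )
        out.append(
            GeneRecord(
                gene_id=gid,
                transcript_id=row.get("transcript_id", gid) or gid,
                cds=seqs[gid],
                exon_count=int(row["exon_count"]),
                exon_intervals=intervals,
                intron_lengths=introns,
            )
        )
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score[, strand]]]) rows as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out


def write_snps(snps: Sequence[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": s.gene_id,
            "cds_pos_0based": s.cds_pos,
            "ref": s.ref,
            "alt": s.alt,
            "maf": s.maf,
            "consequence": s.consequence,
        }
        for s in snps
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "cds_pos_0based", "ref", "alt", "maf", "consequence"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snps(path: str | Path) -> list[SnpRecord]:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        SnpRecord(
            str(r.gene_id),
            int(r.cds_pos_0based),
            str(r.ref),
            str(r.alt),
            float(r.maf),
            str(r.consequence),
        )
        for r in table.itertuples()
    ]


def write_cohort(cohort, out_dir: str | Path) -> None:
    """Serialize a synthetic cohort: FASTA, BED, TSV tables, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(((g.gene_id, g.cds) for g in cohort.genes), out / "cds.fasta")
    write_fasta(
        ((a.ortholog_id, a.ortholog_row.replace("-", "")) for a in cohort.ortholog_pairs),
        out / "orthologs.fasta",
    )
    write_architecture(cohort.genes, out / "architecture.tsv")
    exon_rows = []
    for g in cohort.genes:
        chrom, g0, _ = cohort.gene_intervals[g.gene_id]
        intron_shift = 0
        for i, (a, b) in enumerate(g.exon_intervals):
            start = g0 + a + intron_shift
            exon_rows.append((chrom, start, start + (b - a), f"{g.gene_id}_exon{i}"))
            if i < len(g.intron_lengths):
                intron_shift += g.intron_lengths[i]
    write_bed(exon_rows, out / "exons.bed")
    write_bed(cohort.retro_annotations, out / "retrocopies.bed")
    write_bed(
        [(c, s, e, gid) for gid, (c, s, e) in sorted(cohort.gene_intervals.items())],
        out / "genes.bed",
    )
    write_snps(cohort.snp_table, out / "snps.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t")
    (out / "config.json").write_text(cohort.config.echo() + "\n")
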