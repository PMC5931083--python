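"""File-format helpers: FASTA, FASTQ, GFF3, AGP, blast-style hit tables.

Internal coordinates are 0-based half-open everywhere; GFF3 and AGP are
converted to their 1-based inclusive conventions here and nowhere else.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .covpav import GeneModel
from .novelseq import PanBuild, TaxHit


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads, path1, path2) -> None:
    """Write simulated read pairs to a pair of FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in reads:
            q1 = "I" * len(pair.mate1)
            q2 = "I" * len(pair.mate2)
            f1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{q1}\n")
            f2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{q2}\n")


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as gene/mRNA/CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};origin={g.origin}"
            fh.write(
                f"{g.seq_name}\tpanpav\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.seq_name}\tpanpav\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.cds:
                fh.write(
                    f"{g.seq_name}\tpanpav\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Read gene models, picking one representative transcript per gene.

    When a gene has several mRNAs, the transcript with the largest total
    CDS length represents the gene (ties by transcript id), mirroring the
    longest-ORF representative convention of the annotation this format
    carries.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for g in db.features_of_type("gene"):
        best_cds: list[tuple[int, int]] = []
        best_key = None
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            cds = sorted((c.start - 1, c.end) for c in db.children(t, featuretype="CDS"))
            key = (-sum(e - s for s, e in cds), t.id)
            if best_key is None or key < best_key:
                best_key, best_cds = key, cds
        origin = (g.attributes.get("origin") or ["reference"])[0]
        out.append(
            GeneModel(
                gene_id=g.id,
                seq_name=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                cds=tuple(best_cds),
                origin=origin,
            )
        )
    return out


def write_agp(build: PanBuild, path) -> None:
    """Write the novel-scaffold layout as AGP 2.1 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        part = 0
        prev_end = 0
        for cid, off, length in build.offsets:
            if off > prev_end:
                part += 1
                fh.write(
                    f"{build.novel_name}\t{prev_end + 1}\t{off}\t{part}\tU\t"
                    f"{off - prev_end}\tscaffold\tyes\tna\n"
                )
            part += 1
            fh.write(
                f"{build.novel_name}\t{off + 1}\t{off + length}\t{part}\tW\t"
                f"{cid}\t1\t{length}\t+\n"
            )
            prev_end = off + length


def write_offset_map(build: PanBuild, path) -> None:
    pd.DataFrame(
        build.offsets, columns=["contig_id", "offset", "length"]
    ).to_csv(path, sep="\t", index=False)


def read_tax_hits(path) -> list[TaxHit]:
    """Read a blastn outfmt-6-style table with a trailing lineage column.

    Expected columns: qseqid sseqid qlen length qstart qend sstart send
    pident evalue lineage, where lineage is a semicolon-joined taxon path.
    """
    cols = [
        "qseqid", "sseqid", "qlen", "length", "qstart", "qend",
        "sstart", "send", "pident", "evalue", "lineage",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        lineage = tuple(t.strip() for t in str(row.lineage).split(";") if t.strip())
        if not lineage:
            raise ValueError(f"hit for {row.qseqid} has an empty lineage")
        hits.append(
            TaxHit(
                query=str(row.qseqid),
                subject=str(row.sseqid),
                evalue=float(row.evalue),
                pident=float(row.pident),
                lineage=lineage,
            )
        )
    return hits
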