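"""Standard-format I/O: FASTA, GFF3, TSV matrices with scale sidecars.

Coordinates are 0-based half-open in memory and 1-based closed on disk
(GFF3 convention).  Tabular files are tab-separated UTF-8 with a header
row and '.' decimals, so byte-identical round trips are possible for
deterministic runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import ExpressionMatrix
from .probe_validation import GeneModel

_SOURCE = "spudcoex"


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.chromosome}\t{_SOURCE}\tgene\t{m.start + 1}\t{m.end}\t."
                     f"\t{m.strand}\t.\tID={m.gene_id}\n")
            fh.write(f"{m.chromosome}\t{_SOURCE}\tmRNA\t{m.start + 1}\t{m.end}\t."
                     f"\t{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n")
            for s, e in m.exons:
                fh.write(f"{m.chromosome}\t{_SOURCE}\texon\t{s + 1}\t{e}\t."
                         f"\t{m.strand}\t.\tParent={m.transcript_id}\n")


def read_gff3(path) -> dict[str, GeneModel]:
    """Load gene models through gffutils (1-based closed -> half-open)."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        transcript_id = mrnas[0].id if mrnas else f"{gene.id}.t1"
        parent = mrnas[0] if mrnas else gene
        exons = sorted((f.start - 1, f.end)
                       for f in db.children(parent, featuretype="exon"))
        models[gene.id] = GeneModel(gene.id, gene.seqid, gene.strand,
                                    tuple(exons), transcript_id)
    return models


def spliced_sequences(models: dict[str, GeneModel],
                      genome: dict[str, str]) -> tuple[dict[str, str], dict[str, str]]:
    """Derive spliced transcript and pre-mRNA sequences from the genome."""
    from .probe_validation import reverse_complement

    transcripts, premrnas = {}, {}
    for gid, m in models.items():
        chrom = genome[m.chromosome]
        pre = chrom[m.start:m.end]
        tx = "".join(chrom[s:e] for s, e in m.exons)
        if m.strand == "-":
            pre = reverse_complement(pre)
            tx = reverse_complement(tx)
        transcripts[gid] = tx
        premrnas[gid] = pre
    return transcripts, premrnas


def write_matrix(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep="\t", index_label="feature_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"platform_id": m.platform_id, "scale": m.scale}, indent=1) + "\n")


def read_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return ExpressionMatrix(meta["platform_id"], meta["scale"], df)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
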