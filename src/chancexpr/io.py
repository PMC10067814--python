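"""File formats: GFF3 annotations, FASTA libraries and the TSV tables
exchanged between pipeline stages.

GFF3 is read through :mod:`gffutils`; chromosome lengths come from
``##sequence-region`` directives.  Protein-coding genes carry a ``CDS``
child and optional ``five_prime_UTR``/``three_prime_UTR`` children; RNA
genes are ``gene`` records with an RNA ``biotype``; excluded features
(centromere, telomere, LTR, LTR retrotransposon) are top-level records
of their own type.
"""

from __future__ import annotations

import json

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .landscape import EXCLUDED_TYPES, ExcludedFeature, Gene, GenomeAnnotation


def write_fasta(path, seqs: dict) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


def _gff_line(chrom, source, ftype, start, end, strand, attrs) -> str:
    attr = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{chrom}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr}"


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom, clen in annotation.chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {clen}")
    for g in annotation.genes:
        span_lo, span_hi = g.start, g.end
        for utr in (g.utr5, g.utr3):
            if utr is not None:
                span_lo, span_hi = min(span_lo, utr[0]), max(span_hi, utr[1])
        lines.append(
            _gff_line(g.chrom, "chancexpr", "gene", span_lo, span_hi, g.strand,
                      {"ID": g.gene_id, "biotype": g.gtype})
        )
        if g.gtype == "protein_coding":
            lines.append(
                _gff_line(g.chrom, "chancexpr", "CDS", g.start, g.end, g.strand,
                          {"ID": f"{g.gene_id}.cds", "Parent": g.gene_id})
            )
            if g.utr5 is not None:
                lines.append(
                    _gff_line(g.chrom, "chancexpr", "five_prime_UTR",
                              g.utr5[0], g.utr5[1], g.strand,
                              {"ID": f"{g.gene_id}.utr5", "Parent": g.gene_id})
                )
            if g.utr3 is not None:
                lines.append(
                    _gff_line(g.chrom, "chancexpr", "three_prime_UTR",
                              g.utr3[0], g.utr3[1], g.strand,
                              {"ID": f"{g.gene_id}.utr3", "Parent": g.gene_id})
                )
    for i, f in enumerate(annotation.excluded):
        lines.append(
            _gff_line(f.chrom, "chancexpr", f.ftype, f.start, f.end, "+",
                      {"ID": f"excl{i}"})
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    chrom_lengths = {}
    for d in db.directives:
        parts = d.split()
        if parts and parts[0] == "sequence-region":
            chrom_lengths[parts[1]] = int(parts[3])
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        gtype = feat.attributes.get("biotype", ["protein_coding"])[0]
        utr5 = utr3 = None
        if gtype == "protein_coding":
            cds = list(db.children(feat, featuretype="CDS"))
            if cds:
                start, end = cds[0].start, cds[0].end
            else:
                start, end = feat.start, feat.end
            for u in db.children(feat, featuretype="five_prime_UTR"):
                utr5 = (u.start, u.end)
            for u in db.children(feat, featuretype="three_prime_UTR"):
                utr3 = (u.start, u.end)
        else:
            start, end = feat.start, feat.end
        genes.append(
            Gene(gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                 start=start, end=end, gtype=gtype, utr5=utr5, utr3=utr3)
        )
    excluded = [
        ExcludedFeature(chrom=f.seqid, start=f.start, end=f.end, ftype=f.featuretype)
        for ftype in EXCLUDED_TYPES
        for f in db.features_of_type(ftype)
    ]
    return GenomeAnnotation(genes=genes, excluded=excluded, chrom_lengths=chrom_lengths)
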