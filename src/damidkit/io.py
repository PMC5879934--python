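"""Readers and writers for the standard formats the pipeline consumes.

Gene models travel as GFF3 (1-based closed on disk, converted to 0-based
half-open in memory), genomes as FASTA, expression and tissue matrices as
TSV.  Only the mapping between disk formats and the in-memory containers
lives here; all analysis stays in the topic modules.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GeneModel


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


_GFF_TYPE = {"utr5": "five_prime_UTR", "cds": "CDS", "utr3": "three_prime_UTR"}


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Serialise gene models as GFF3 (mRNA + UTR/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.transcript_id};gene_id={g.gene_id}"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for field, gff_type in _GFF_TYPE.items():
                for s, e in getattr(g, field):
                    fh.write(
                        f"{g.chrom}\t.\t{gff_type}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tParent={g.transcript_id}\n"
                    )


_GFF_FIELD = {"five_prime_UTR": "utr5", "CDS": "cds",
              "three_prime_UTR": "utr3"}


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models (mRNA with five_prime_UTR/CDS/three_prime_UTR).

    Uses gffutils; coordinates convert from 1-based closed to 0-based
    half-open.  Exon features, if present, are ignored (introns are derived
    from the UTR/CDS blocks).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        g = GeneModel(
            transcript_id=feat.id,
            gene_id=feat.attributes.get("gene_id", [feat.id])[0],
            chrom=feat.seqid,
            strand=feat.strand,
            start=feat.start - 1,
            end=feat.end,
        )
        for child in db.children(feat):
            field = _GFF_FIELD.get(child.featuretype)
            if field is not None:
                getattr(g, field).append((child.start - 1, child.end))
        g.utr5.sort(); g.cds.sort(); g.utr3.sort()
        genes.append(g)
    return genes


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV: transcript_id index, fpkm_<genotype> columns plus

    optional log2fc_<mutant> and sig_<mutant> flags.
    """
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError("expression table needs a transcript_id column")
    return df.set_index("transcript_id")


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id",
                float_format="%.6g")


def read_tissue_matrix(path: str | Path) -> pd.DataFrame:
    """Tissue log-ratio matrix: transcripts x tissues, NA = null expression."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tissue_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="transcript_id",
                  float_format="%.6g", na_rep="NA")
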