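"""File-format boundaries: FASTA/FASTQ, GFF3/BED6 annotations, VCF variants,
and the pipeline's tab-separated tables.

Conventions at the boundary: GFF3 is 1-based inclusive on disk and converted
to the internal 0-based half-open coordinates; BED6 is already 0-based
half-open; VCF positions stay 1-based as in the format. Sequences are
normalized to the DNA alphabet on read; small-RNA sequences are reported in
the RNA alphabet in output tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import MatureAnnotation, ReferenceBundle, to_dna

FASTQ_QUALITY = 40  # constant quality for simulated reads


# ---------------------------------------------------------------------------
# reads and genome
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write reads as FASTQ with a constant high quality value."""
    def _records():
        for name, seq in records:
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [FASTQ_QUALITY] * len(seq)
            yield rec
    SeqIO.write(_records(), str(path), "fastq")


def read_reads(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ (sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_genome(path: str | Path, ref: ReferenceBundle) -> None:
    write_fasta(path, [(ref.chrom, ref.genome)])


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def write_gff3(path: str | Path, ref: ReferenceBundle) -> None:
    """Write annotations as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in ref.annotations:
            fh.write(
                "\t".join(
                    [
                        a.chrom, "mirmove", "miRNA",
                        str(a.start + 1), str(a.end), ".", a.strand, ".",
                        f"ID={a.id}",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path, genome: dict[str, str]) -> ReferenceBundle:
    """Read miRNA annotations from GFF3 against a single-chromosome genome."""
    annotations = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            name = attr_map.get("ID") or attr_map.get("Name")
            if name is None:
                raise ValueError(f"GFF3 feature without ID/Name: {line!r}")
            start0, end0 = int(start) - 1, int(end)
            seq = genome[chrom][start0:end0]
            if strand == "-":
                from .reference import revcomp
                seq = revcomp(seq)
            annotations.append(
                MatureAnnotation(name, chrom, start0, end0, strand, seq)
            )
    if not annotations:
        raise ValueError(f"no annotations found in {path}")
    chrom = annotations[0].chrom
    bundle = ReferenceBundle(genome[chrom], annotations, chrom=chrom)
    bundle.validate()
    return bundle


def write_bed6(path: str | Path, ref: ReferenceBundle) -> None:
    """Write annotations as BED6 (0-based half-open, as internal)."""
    with open(path, "w") as fh:
        for a in ref.annotations:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.id}\t0\t{a.strand}\n"
            )


def read_bed6(path: str | Path, genome: dict[str, str]) -> ReferenceBundle:
    from .reference import revcomp

    annotations = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            start0, end0 = int(start), int(end)
            seq = genome[chrom][start0:end0]
            if strand == "-":
                seq = revcomp(seq)
            annotations.append(
                MatureAnnotation(name, chrom, start0, end0, strand, seq)
            )
    if not annotations:
        raise ValueError(f"no annotations found in {path}")
    chrom = annotations[0].chrom
    bundle = ReferenceBundle(genome[chrom], annotations, chrom=chrom)
    bundle.validate()
    return bundle


def read_annotations(path: str | Path, genome: dict[str, str]) -> ReferenceBundle:
    """Dispatch on extension: .gff/.gff3 -> GFF3, .bed -> BED6."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path, genome)
    if suffix == ".bed":
        return read_bed6(path, genome)
    raise ValueError(f"unrecognized annotation format: {path}")


# ---------------------------------------------------------------------------
# variants (VCF 4.2 with INFO AF and EFF)
# ---------------------------------------------------------------------------

def write_vcf(
    path: str | Path, variants: pd.DataFrame, contigs: Sequence[tuple[str, int]] = ()
) -> None:
    """Write a variant table (chrom, pos, ref, alt, allele_fraction, effect)
    as minimal VCF 4.2 with INFO keys AF and EFF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"AF={row.allele_fraction:g};EFF={row.effect}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into the internal variant table via pysam."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            eff = rec.info.get("EFF", "other")
            if isinstance(eff, tuple):
                eff = eff[0]
            for alt in rec.alts or ():
                rows.append(
                    (
                        rec.chrom, rec.pos, rec.ref, alt,
                        float(af) if af is not None else float("nan"),
                        str(eff),
                    )
                )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "allele_fraction", "effect"]
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_design(path: str | Path) -> dict[str, str]:
    """Sample design TSV (columns sample_id, genotype) -> mapping."""
    df = read_table(path)
    missing = {"sample_id", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return dict(zip(df["sample_id"].astype(str), df["genotype"].astype(str)))
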