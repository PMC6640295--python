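"""Readers and writers for the standard formats the pipeline touches.

Everything downstream works on the small set of domain types defined here:
:class:`GeneModel` (representative splice model of a protein-coding gene),
:class:`VariantRecord` (one homozygous strain call), and :class:`HitRecord`
(one row of a BLAST ``outfmt 6``-like protein similarity table).

Coordinate convention: 1-based inclusive genomic coordinates everywhere
(GFF3 convention); VCF positions are used as-is.  CDS coordinates are
0-based offsets into the spliced coding sequence in transcript orientation.
Indels are VCF-style left-anchored (first base shared between ref and alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Representative splice model of one protein-coding gene.

    ``cds_intervals`` are (start, end) pairs, 1-based inclusive, listed in
    transcript order: ascending genomic position on the + strand, descending
    on the − strand.  ``gene_start``/``gene_end`` span the whole gene
    feature (used for the gene-length covariate); they default to the CDS
    extent when the GFF3 carries no separate gene feature.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    is_representative: bool = True
    gene_start: int = 0
    gene_end: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 >= s2:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        expect = tuple(ivs) if self.strand == "+" else tuple(ivs[::-1])
        if tuple(self.cds_intervals) != expect:
            raise ValueError(
                f"CDS intervals of {self.gene_id} not in transcript order"
            )
        if self.gene_start == 0:
            object.__setattr__(self, "gene_start", min(s for s, _ in ivs))
        if self.gene_end == 0:
            object.__setattr__(self, "gene_end", max(e for _, e in ivs))

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def gene_length(self) -> int:
        return self.gene_end - self.gene_start + 1

    def cds_sequence(self, chromosome_seq: str) -> str:
        """Spliced CDS in transcript orientation from the chromosome string."""
        parts = [chromosome_seq[s - 1 : e] for s, e in sorted(self.cds_intervals)]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq

    def genomic_to_cds(self, position: int) -> int | None:
        """0-based CDS offset of a genomic position, None if non-coding."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= position <= e:
                if self.strand == "+":
                    return offset + (position - s)
                return offset + (e - position)
            offset += e - s + 1
        return None

    def cds_to_genomic(self, index: int) -> int:
        """Genomic position of a 0-based CDS offset."""
        if index < 0 or index >= self.cds_length:
            raise IndexError(f"CDS offset {index} outside {self.gene_id}")
        offset = 0
        for s, e in self.cds_intervals:
            length = e - s + 1
            if index < offset + length:
                within = index - offset
                return s + within if self.strand == "+" else e - within
            offset += length
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class VariantRecord:
    """One quality-filtered call of a fully homozygous inbred strain."""

    strain_id: str
    chromosome: str
    position: int  # 1-based genomic
    ref_allele: str
    alt_allele: str
    quality: float

    def __post_init__(self):
        if self.quality < 0:
            raise ValueError("phred quality must be >= 0")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "indel"

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class MissingCall:
    """A genomic position at which a strain has no reliable base call."""

    strain_id: str
    chromosome: str
    position: int


@dataclass(frozen=True)
class HitRecord:
    """One row of a BLAST tabular (outfmt-6-like) protein hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    bit_score: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")
        if self.aligned_length < 1:
            raise ValueError("aligned length must be >= 1")


def variant_cds_edit(model: GeneModel, ref_cds: str, v: VariantRecord):
    """Map a genomic variant onto the transcript-oriented CDS.

    Returns (cds_offset, ref_segment, alt_segment) with alleles in
    transcript orientation (reverse-complemented for − strand genes), or
    None when the variant does not lie contiguously within the CDS.
    Raises ValueError when the mapped reference segment disagrees with the
    reference CDS.
    """
    span = range(v.position, v.position + len(v.ref_allele))
    offsets = [model.genomic_to_cds(p) for p in span]
    if any(o is None for o in offsets):
        return None
    if model.strand == "+":
        if offsets != list(range(offsets[0], offsets[0] + len(offsets))):
            return None
        start, ref_seg, alt_seg = offsets[0], v.ref_allele, v.alt_allele
    else:
        if offsets != list(range(offsets[0], offsets[0] - len(offsets), -1)):
            return None
        start = offsets[-1]
        ref_seg = reverse_complement(v.ref_allele)
        alt_seg = reverse_complement(v.alt_allele)
    if ref_cds[start : start + len(ref_seg)] != ref_seg.upper():
        raise ValueError(
            f"{v.strain_id}@{v.chromosome}:{v.position}: ref allele "
            f"{v.ref_allele!r} disagrees with reference CDS of {model.gene_id}"
        )
    return start, ref_seg.upper(), alt_seg.upper()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3, one per representative mRNA.

    When a gene carries several mRNAs, an mRNA with a truthy
    ``representative`` attribute wins, otherwise the lexicographically
    smallest mRNA ID.  Genes whose CDS length is not divisible by 3 are
    excluded with a logged warning.  Unparseable lines raise
    :class:`FormatError` with the line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        rep = [m for m in mrnas if m.attributes.get("representative", ["false"])[0].lower() in ("true", "1")]
        mrna = rep[0] if rep else min(mrnas, key=lambda m: m.id)
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = [(c.start, c.end) for c in cds]
        if gene.strand == "-":
            intervals = intervals[::-1]
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            cds_intervals=tuple(intervals),
            is_representative=True,
            gene_start=gene.start,
            gene_end=gene.end,
        )
        if model.cds_length % 3 != 0:
            logger.warning(
                "gene %s excluded: CDS length %d not divisible by 3",
                gene.id,
                model.cds_length,
            )
            continue
        models.append(model)
    models.sort(key=lambda m: (m.chromosome, min(s for s, _ in m.cds_intervals)))
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS features for each model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chromosome, g.gene_start)):
            cols = [m.chromosome, "pollenselect", "gene", str(m.gene_start), str(m.gene_end), ".", m.strand, "."]
            fh.write("\t".join(cols + [f"ID={m.gene_id}"]) + "\n")
            mrna_id = f"{m.gene_id}.1"
            cols[2] = "mRNA"
            fh.write("\t".join(cols + [f"ID={mrna_id};Parent={m.gene_id};representative=true"]) + "\n")
            phase = 0
            for s, e in m.cds_intervals:
                row = [m.chromosome, "pollenselect", "CDS", str(s), str(e), ".", m.strand, str(phase)]
                fh.write("\t".join(row + [f"ID=cds-{mrna_id};Parent={mrna_id}"]) + "\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["strain", "chrom", "pos", "ref", "alt", "qual"]


def read_variants(
    path: str | Path,
    min_quality: float = 25.0,
    with_missing: bool = False,
):
    """Read strain variant calls from VCF or the simple TSV dialect.

    Only records with phred quality >= ``min_quality`` are retained;
    multi-allelic records are split into one record per alternative allele.
    Records with no quality value fail the filter; their count is logged.
    TSV rows with alt ``.`` denote missing calls and are returned separately
    when ``with_missing`` is true.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        records, missing, no_qual = _read_vcf(path, min_quality)
    else:
        records, missing, no_qual = _read_variant_tsv(path, min_quality)
    if no_qual:
        logger.warning("%s: %d records without quality failed the filter", path, no_qual)
    if with_missing:
        return records, missing
    return records


def _read_vcf(path: Path, min_quality: float):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    records: list[VariantRecord] = []
    missing: list[MissingCall] = []
    no_qual = 0
    for var in vcf:
        if var.QUAL is None:
            no_qual += 1
            continue
        if var.QUAL < min_quality:
            continue
        genotypes = var.genotypes  # [[a, b, phased], ...]
        for strain, gt in zip(strains, genotypes):
            alleles = set(gt[:-1])
            if -1 in alleles:
                missing.append(MissingCall(strain, var.CHROM, var.POS))
                continue
            # inbred strains: any non-reference allele is treated as a
            # homozygous carrier call
            for a in sorted(alleles - {0}):
                records.append(
                    VariantRecord(
                        strain_id=strain,
                        chromosome=var.CHROM,
                        position=var.POS,
                        ref_allele=var.REF,
                        alt_allele=var.ALT[a - 1],
                        quality=float(var.QUAL),
                    )
                )
    return records, missing, no_qual


def _read_variant_tsv(path: Path, min_quality: float):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return [], [], 0
    if list(df.columns) != _VARIANT_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_VARIANT_COLUMNS}, got {list(df.columns)}"
        )
    records: list[VariantRecord] = []
    missing: list[MissingCall] = []
    no_qual = 0
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if row.alt == ".":
            missing.append(MissingCall(row.strain, row.chrom, pos))
            continue
        if pd.isna(row.qual) or row.qual in (".", ""):
            no_qual += 1
            continue
        qual = float(row.qual)
        if qual < min_quality:
            continue
        for alt in str(row.alt).split(","):
            records.append(
                VariantRecord(
                    strain_id=row.strain,
                    chromosome=row.chrom,
                    position=pos,
                    ref_allele=row.ref,
                    alt_allele=alt,
                    quality=qual,
                )
            )
    return records, missing, no_qual


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        (r.strain_id, r.chromosome, r.position, r.ref_allele, r.alt_allele, r.quality)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

_EXPRESSION_COLUMNS = ["gene_id", "tissue", "level", "presence"]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Long-form expression table: gene_id, tissue, level, presence.

    Presence scores must lie in [0, 1].  Absent gene x tissue pairs are
    interpreted downstream as (level 0, presence 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str})
    if list(df.columns) != _EXPRESSION_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_EXPRESSION_COLUMNS}, got {list(df.columns)}"
        )
    if ((df["presence"] < 0) | (df["presence"] > 1)).any():
        bad = df[(df["presence"] < 0) | (df["presence"] > 1)].iloc[0]
        raise FormatError(
            f"{path}: presence score {bad['presence']} outside [0, 1] "
            f"for {bad['gene_id']}/{bad['tissue']}"
        )
    if (df["level"] < 0).any():
        raise FormatError(f"{path}: negative expression level")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, _EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """BLAST outfmt-6-like table: 12 standard columns, or the minimal 5
    (qseqid sseqid pident length bitscore).  No header row."""
    hits: list[HitRecord] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 12:
                q, s, pid, length, bits = cols[0], cols[1], cols[2], cols[3], cols[11]
            elif len(cols) == 5:
                q, s, pid, length, bits = cols
            else:
                raise FormatError(f"{path}:{lineno}: expected 5 or >=12 columns")
            hits.append(
                HitRecord(
                    query_id=q,
                    subject_id=s,
                    percent_identity=float(pid),
                    aligned_length=int(length),
                    bit_score=float(bits),
                )
            )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}"
                f"\t{h.aligned_length}\t{h.bit_score:.1f}\n"
            )
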