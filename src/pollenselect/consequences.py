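"""Per-strain coding sequences and putatively deleterious alleles.

Two gene-level scores over a panel of homozygous inbred strains:

* premature stop codons — the number of unique alternative alleles (keyed
  by the causal CDS position(s) and alternative base(s)) that create a stop
  codon before the reference terminal stop, applying SNPs only; reported
  both raw and relative to the strain count;
* frameshifts — the proportion of strains carrying at least one CDS indel
  whose length change is not a multiple of 3.

The two metrics are deliberately non-overlapping: indels never contribute
to the stop metric and SNPs never to the frameshift metric.  A SNP that
alters the reference terminal stop codon is a stop-loss, not a premature
stop, and is ignored here.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codons import STOP_CODONS
from .io_formats import GeneModel, VariantRecord, variant_cds_edit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrainCDS:
    gene_id: str
    strain_id: str
    sequence: str
    n_rejected: int = 0  # variants whose ref allele disagreed with the reference


@dataclass(frozen=True)
class DeleteriousAlleleStats:
    gene_id: str
    unique_stop_alleles: int
    stop_allele_frequency: float
    frameshift_frequency: float
    n_strains: int


def build_strain_cds(
    model: GeneModel,
    genome: Mapping[str, str],
    strain_variants: Sequence[VariantRecord],
    strain_id: str = "",
) -> StrainCDS:
    """Apply one strain's filtered variants to the reference CDS.

    SNPs are substituted at their CDS-mapped positions; indels are applied
    left-anchored.  Variants whose reference allele disagrees with the
    reference sequence are rejected and counted, not fatal.
    """
    ref_cds = model.cds_sequence(genome[model.chromosome])
    edits = []
    rejected = 0
    for v in strain_variants:
        try:
            edit = variant_cds_edit(model, ref_cds, v)
        except ValueError as exc:
            logger.warning("rejected variant: %s", exc)
            rejected += 1
            continue
        if edit is not None:
            edits.append(edit)
    seq = ref_cds
    for start, ref_seg, alt_seg in sorted(edits, reverse=True):
        seq = seq[:start] + alt_seg + seq[start + len(ref_seg) :]
    return StrainCDS(
        gene_id=model.gene_id,
        strain_id=strain_id or (strain_variants[0].strain_id if strain_variants else ""),
        sequence=seq,
        n_rejected=rejected,
    )


def score_premature_stops(
    model: GeneModel,
    genome: Mapping[str, str],
    variants_by_strain: Mapping[str, Sequence[VariantRecord]],
    n_strains: int,
) -> tuple[int, float]:
    """Unique premature-stop alternative alleles over a strain panel.

    Only SNPs are considered.  Within each strain, all of that strain's
    SNPs in a codon are applied jointly; a codon (before the terminal one)
    that becomes a stop contributes an allele keyed by its causal
    (CDS position, alt base) pairs.  The frequency is the unique-allele
    count divided by ``n_strains``.
    """
    ref_cds = model.cds_sequence(genome[model.chromosome])
    last_codon = len(ref_cds) // 3 - 1
    unique: set[tuple] = set()
    for strain, variants in variants_by_strain.items():
        by_codon: dict[int, list[tuple[int, str]]] = defaultdict(list)
        for v in variants:
            if v.kind != "SNP":
                continue
            try:
                edit = variant_cds_edit(model, ref_cds, v)
            except ValueError:
                continue
            if edit is None:
                continue
            start, _, alt = edit
            by_codon[start // 3].append((start, alt))
        for codon_idx, snps in by_codon.items():
            if codon_idx >= last_codon:
                continue  # terminal stop changes are stop-loss, not premature
            codon = list(ref_cds[codon_idx * 3 : codon_idx * 3 + 3])
            causal = []
            for start, alt in snps:
                if codon[start % 3] != alt:
                    causal.append((start, alt))
                codon[start % 3] = alt
            if "".join(codon) in STOP_CODONS and causal:
                unique.add(tuple(sorted(causal)))
    return len(unique), len(unique) / n_strains


def score_frameshifts(
    model: GeneModel,
    variants_by_strain: Mapping[str, Sequence[VariantRecord]],
    n_strains: int,
) -> float:
    """Proportion of strains carrying >=1 frame-disrupting CDS indel."""
    carriers = 0
    for variants in variants_by_strain.values():
        for v in variants:
            if v.kind != "indel" or v.length_change % 3 == 0:
                continue
            if len(v.ref_allele) > 1:  # deletion: bases after the anchor
                affected = range(v.position + 1, v.position + len(v.ref_allele))
            else:  # insertion: the anchor base
                affected = (v.position,)
            if any(model.genomic_to_cds(p) is not None for p in affected):
                carriers += 1
                break
    return carriers / n_strains


def group_variants(
    records: Iterable[VariantRecord],
) -> dict[str, dict[str, list[VariantRecord]]]:
    """chromosome -> strain -> variants, for per-gene slicing."""
    out: dict[str, dict[str, list[VariantRecord]]] = defaultdict(lambda: defaultdict(list))
    for r in records:
        out[r.chromosome][r.strain_id].append(r)
    return out


def deleterious_table(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    records: Iterable[VariantRecord],
    strains: Sequence[str],
) -> pd.DataFrame:
    """Per-gene deleterious-allele scores across the strain panel."""
    grouped = group_variants(records)
    n = len(strains)
    rows = []
    for m in models:
        lo = min(s for s, _ in m.cds_intervals)
        hi = max(e for _, e in m.cds_intervals)
        per_strain = {
            strain: [v for v in variants if lo - 1 <= v.position <= hi]
            for strain, variants in grouped.get(m.chromosome, {}).items()
        }
        count, freq = score_premature_stops(m, genome, per_strain, n)
        fs = score_frameshifts(m, per_strain, n)
        rows.append((m.gene_id, count, freq, fs, n))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "unique_stop_alleles",
            "stop_allele_frequency",
            "frameshift_frequency",
            "n_strains",
        ],
    )
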