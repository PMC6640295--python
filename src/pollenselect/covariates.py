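"""The six genomic covariates used to control group comparisons:
expression level, GC content, RSCU (codon-bias) variance, gene length,
average intron length, and 100-kb gene density.

GC content is computed over the unspliced genomic gene span by default
(configurable to the spliced CDS); RSCU variance follows the standard
definition with stop codons excluded and codons of unused amino acids
ignored; gene density is the gene count of the fixed 100-kb window
containing the gene start.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, FAMILY_SIZE, STOP_CODONS
from .io_formats import GeneModel


def gc_content(sequence: str) -> float:
    """Percent G+C among unambiguous bases."""
    seq = sequence.upper()
    counts = Counter(seq)
    unambiguous = sum(counts[b] for b in "ACGT")
    if unambiguous == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / unambiguous


def rscu_values(cds: str) -> dict[str, float]:
    """RSCU per sense codon occurring in families of used amino acids.

    RSCU(c) = count(c) * k_a / sum of counts over the family of c's amino
    acid, with k_a the family size.  Codons of amino acids absent from the
    gene are excluded entirely (their RSCU would be 0/0)."""
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    counts: Counter[str] = Counter()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS or codon not in CODON_TO_AA:
            continue
        counts[codon] += 1
    family_totals: Counter[str] = Counter()
    for codon, n in counts.items():
        family_totals[CODON_TO_AA[codon]] += n
    out: dict[str, float] = {}
    for codon, aa in CODON_TO_AA.items():
        if aa == "*" or family_totals[aa] == 0:
            continue
        out[codon] = counts[codon] * FAMILY_SIZE[aa] / family_totals[aa]
    return out

def rscu_variance(cds: str) -> float:
    """Population variance of the within-gene RSCU values (codon-bias
    measure; 0 when every used family is used uniformly)."""
    values = np.array(list(rscu_values(cds).values()))
    return float(np.var(values))


def gene_density(
    models: Sequence[GeneModel], window: int = 100_000
) -> dict[str, int]:
    """Genes per fixed window, attributed to each gene by the window
    containing its start.  Windows are half-open: [0, w), [w, 2w), ..."""
    window_of = {m.gene_id: (m.chromosome, m.gene_start // window) for m in models}
    counts = Counter(window_of.values())
    return {gid: counts[w] for gid, w in window_of.items()}


def intron_stats(model: GeneModel) -> tuple[int, float]:
    """(gene_length, average intron length); 0.0 when single-interval."""
    ivs = sorted(model.cds_intervals)
    gaps = [s2 - e1 - 1 for (_, e1), (s2, _) in zip(ivs, ivs[1:])]
    avg = float(np.mean(gaps)) if gaps else 0.0
    return model.gene_length, avg


def covariate_table(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    expression_levels: Mapping[str, float],
    gc_on: str = "gene",
    window: int = 100_000,
) -> pd.DataFrame:
    """Assemble the six per-gene covariates into one frame.

    ``gc_on`` selects the sequence GC content is computed on: the unspliced
    genomic gene span ("gene", default) or the spliced CDS ("cds").
    """
    density = gene_density(models, window=window)
    rows = []
    for m in models:
        chrom = genome[m.chromosome]
        cds = m.cds_sequence(chrom)
        span = chrom[m.gene_start - 1 : m.gene_end]
        gene_len, avg_intron = intron_stats(m)
        rows.append(
            (
                m.gene_id,
                float(expression_levels.get(m.gene_id, 0.0)),
                gc_content(span if gc_on == "gene" else cds),
                rscu_variance(cds),
                gene_len,
                avg_intron,
                density[m.gene_id],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "expression_level",
            "gc_percent",
            "rscu_variance",
            "gene_length",
            "avg_intron_length",
            "gene_density",
        ],
    )
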