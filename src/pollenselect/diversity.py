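"""Site-class diversity: degeneracy partitioning, per-gene π and
Watterson's θ at 0-fold (nonsynonymous) and 4-fold (synonymous) sites, and
site-frequency spectra.

Degeneracy is assigned from the reference codons of the standard nuclear
code.  Codons carrying more than one SNP across the strain panel are
masked entirely (all three positions), as are codons containing ambiguity
codes.  Sites with a missing call in any strain, or with more than one
alternative allele, are excluded and the site tally L decremented.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import STOP_CODONS, position_degeneracy
from .consequences import group_variants
from .io_formats import GeneModel, MissingCall, VariantRecord, variant_cds_edit

ZERO_FOLD = "zero_fold"
FOUR_FOLD = "four_fold"
OTHER = "other"
MASKED = "masked"


@dataclass
class SiteClassMap:
    gene_id: str
    classes: list[str]  # per CDS position
    masked_codons: dict[int, str] = field(default_factory=dict)  # codon idx -> reason

    def count(self, cls: str) -> int:
        return sum(1 for c in self.classes if c == cls)


@dataclass
class SFSPair:
    """Synonymous and nonsynonymous site-frequency spectra of one gene or
    gene group, with site tallies and optional divergence counts."""

    n: int
    folded: bool
    sfs_n: np.ndarray
    sfs_s: np.ndarray
    L_n: float
    L_s: float
    D_n: float = 0.0
    D_s: float = 0.0

    @property
    def n_classes(self) -> int:
        return self.n // 2 if self.folded else self.n - 1

    @property
    def S_n(self) -> int:
        return int(self.sfs_n.sum())

    @property
    def S_s(self) -> int:
        return int(self.sfs_s.sum())

    def __add__(self, other: "SFSPair") -> "SFSPair":
        if (self.n, self.folded) != (other.n, other.folded):
            raise ValueError("cannot add spectra with different n or folding")
        return SFSPair(
            n=self.n,
            folded=self.folded,
            sfs_n=self.sfs_n + other.sfs_n,
            sfs_s=self.sfs_s + other.sfs_s,
            L_n=self.L_n + other.L_n,
            L_s=self.L_s + other.L_s,
            D_n=self.D_n + other.D_n,
            D_s=self.D_s + other.D_s,
        )


def empty_sfs(n: int, folded: bool = True) -> SFSPair:
    k = n // 2 if folded else n - 1
    return SFSPair(n=n, folded=folded, sfs_n=np.zeros(k), sfs_s=np.zeros(k), L_n=0.0, L_s=0.0)


def fold_sfs(sfs: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded spectrum (classes 1..n-1) to minor-allele classes
    1..n//2."""
    folded = np.zeros(n // 2)
    for i in range(1, n):
        folded[min(i, n - i) - 1] += sfs[i - 1]
    return folded


@dataclass(frozen=True)
class DiversityStats:
    gene_id: str
    n: int
    L_n: float
    L_s: float
    S_n: int
    S_s: int
    theta_n: float
    theta_s: float
    pi_n: float
    pi_s: float


def harmonic_number(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-site Watterson's θ = S / (a_{n-1} L)."""
    if n < 2:
        raise ValueError("need at least two sequences")
    if L <= 0:
        raise ValueError("no sites")
    return S / (harmonic_number(n - 1) * L)


def nucleotide_diversity(
    allele_counts: Iterable[Mapping[str, int]], n: int, L: float
) -> float:
    """Per-site π from per-site allele counts (average pairwise difference).

    Each element maps allele -> count over the n strains; monomorphic sites
    may be omitted since they contribute zero.
    """
    if n < 2:
        raise ValueError("need at least two sequences")
    if L <= 0:
        raise ValueError("no sites")
    total_pairs = n * (n - 1) / 2
    pi = 0.0
    for counts in allele_counts:
        same = sum(c * (c - 1) / 2 for c in counts.values())
        pi += 1.0 - same / total_pairs
    return pi / L


def pi_from_sfs(sfs: np.ndarray, n: int, L: float) -> float:
    """π from a spectrum: Σ_i i(n-i) sfs[i] / C(n,2) / L.  The weight
    i(n-i) is symmetric in i ↔ n-i, so the formula holds folded or not."""
    if L <= 0:
        raise ValueError("no sites")
    i = np.arange(1, len(sfs) + 1)
    return float(np.sum(i * (n - i) * sfs) / (n * (n - 1) / 2) / L)


# ---------------------------------------------------------------------------
# per-gene machinery
# ---------------------------------------------------------------------------


def classify_sites(reference_cds: str, snp_offsets: Iterable[int]) -> SiteClassMap:
    """Degeneracy class per CDS position, with >1-SNP codons masked.

    ``snp_offsets`` are the 0-based CDS offsets that are polymorphic
    anywhere in the panel.  The terminal stop codon is classified as
    ``other`` (it is neither a 0-fold nor a 4-fold coding site).
    """
    reference_cds = reference_cds.upper()
    if len(reference_cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    snps_per_codon: dict[int, int] = defaultdict(int)
    for off in set(snp_offsets):
        snps_per_codon[off // 3] += 1
    classes: list[str] = []
    masked: dict[int, str] = {}
    for ci in range(len(reference_cds) // 3):
        codon = reference_cds[ci * 3 : ci * 3 + 3]
        if snps_per_codon[ci] > 1:
            masked[ci] = "multi_snp_codon"
            classes.extend([MASKED] * 3)
            continue
        if any(b not in "ACGT" for b in codon):
            masked[ci] = "ambiguous_codon"
            classes.extend([MASKED] * 3)
            continue
        if codon in STOP_CODONS:
            classes.extend([OTHER] * 3)
            continue
        classes.extend(position_degeneracy(codon, p) for p in range(3))
    return SiteClassMap(gene_id="", classes=classes, masked_codons=masked)


def build_sfs(
    site_alts: Mapping[int, Mapping[str, str]],
    site_class_map: SiteClassMap,
    n: int,
    fold: bool = True,
    missing_sites: Mapping[int, set] | None = None,
) -> SFSPair:
    """Site-frequency spectra from per-site strain alt calls.

    ``site_alts`` maps CDS offset -> {strain: alt base}; strains absent at
    an offset carry the reference.  Sites with a missing call in any strain
    and sites with more than one distinct alt are excluded with L
    decremented.  Folding uses the minor allele count.
    """
    missing_sites = missing_sites or {}
    k = n // 2 if fold else n - 1
    sfs = {ZERO_FOLD: np.zeros(k), FOUR_FOLD: np.zeros(k)}
    L = {ZERO_FOLD: float(site_class_map.count(ZERO_FOLD)), FOUR_FOLD: float(site_class_map.count(FOUR_FOLD))}
    for off, strains_missing in missing_sites.items():
        cls = site_class_map.classes[off]
        if cls in L and strains_missing:
            L[cls] -= 1
    for off, alts in site_alts.items():
        cls = site_class_map.classes[off]
        if cls not in sfs:
            continue
        if missing_sites.get(off):
            continue  # already excluded from L above
        distinct = set(alts.values())
        if len(distinct) > 1:  # triallelic
            L[cls] -= 1
            continue
        i = len(alts)
        if i == 0 or i >= n:
            continue  # monomorphic in the panel
        idx = (min(i, n - i) if fold else i) - 1
        sfs[cls][idx] += 1
    return SFSPair(
        n=n,
        folded=fold,
        sfs_n=sfs[ZERO_FOLD],
        sfs_s=sfs[FOUR_FOLD],
        L_n=L[ZERO_FOLD],
        L_s=L[FOUR_FOLD],
    )


def gene_site_alts(
    model: GeneModel,
    ref_cds: str,
    variants_by_strain: Mapping[str, Sequence[VariantRecord]],
) -> dict[int, dict[str, str]]:
    """CDS offset -> {strain: transcript-oriented alt base} for SNPs."""
    out: dict[int, dict[str, str]] = defaultdict(dict)
    for strain, variants in variants_by_strain.items():
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
            out[start][strain] = alt
    return dict(out)


def gene_diversity(
    model: GeneModel,
    genome: Mapping[str, str],
    variants_by_strain: Mapping[str, Sequence[VariantRecord]],
    n: int,
    fold: bool = True,
    missing_calls: Sequence[MissingCall] = (),
) -> tuple[SFSPair, DiversityStats]:
    """SFS and diversity statistics of one gene over the strain panel."""
    ref_cds = model.cds_sequence(genome[model.chromosome])
    site_alts = gene_site_alts(model, ref_cds, variants_by_strain)
    missing_sites: dict[int, set] = defaultdict(set)
    for mc in missing_calls:
        off = model.genomic_to_cds(mc.position)
        if off is not None:
            missing_sites[off].add(mc.strain_id)
    cmap = classify_sites(ref_cds, site_alts.keys())
    cmap.gene_id = model.gene_id
    pair = build_sfs(site_alts, cmap, n, fold=fold, missing_sites=missing_sites)
    stats = DiversityStats(
        gene_id=model.gene_id,
        n=n,
        L_n=pair.L_n,
        L_s=pair.L_s,
        S_n=pair.S_n,
        S_s=pair.S_s,
        theta_n=watterson_theta(pair.S_n, n, pair.L_n) if pair.L_n > 0 else 0.0,
        theta_s=watterson_theta(pair.S_s, n, pair.L_s) if pair.L_s > 0 else 0.0,
        pi_n=pi_from_sfs(pair.sfs_n, n, pair.L_n) if pair.L_n > 0 else 0.0,
        pi_s=pi_from_sfs(pair.sfs_s, n, pair.L_s) if pair.L_s > 0 else 0.0,
    )
    return pair, stats


def diversity_table(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    records: Iterable[VariantRecord],
    strains: Sequence[str],
    fold: bool = True,
    missing_calls: Sequence[MissingCall] = (),
) -> tuple[pd.DataFrame, dict[str, SFSPair]]:
    """Per-gene diversity statistics and SFS over the whole panel."""
    grouped = group_variants(records)
    missing_by_chrom: dict[str, list[MissingCall]] = defaultdict(list)
    for mc in missing_calls:
        missing_by_chrom[mc.chromosome].append(mc)
    n = len(strains)
    rows = []
    spectra: dict[str, SFSPair] = {}
    for m in models:
        lo = min(s for s, _ in m.cds_intervals)
        hi = max(e for _, e in m.cds_intervals)
        per_strain = {
            strain: [v for v in variants if lo <= v.position <= hi]
            for strain, variants in grouped.get(m.chromosome, {}).items()
        }
        mc = [x for x in missing_by_chrom.get(m.chromosome, []) if lo <= x.position <= hi]
        pair, stats = gene_diversity(m, genome, per_strain, n, fold=fold, missing_calls=mc)
        spectra[m.gene_id] = pair
        rows.append(
            (m.gene_id, n, stats.L_n, stats.L_s, stats.S_n, stats.S_s,
             stats.theta_n, stats.theta_s, stats.pi_n, stats.pi_s)
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "n", "L_n", "L_s", "S_n", "S_s",
                 "theta_n", "theta_s", "pi_n", "pi_s"],
    )
    return df, spectra
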