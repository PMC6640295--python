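"""Seeded synthetic inputs with the statistical structure the analysis
assumes: a multi-chromosome gene complement with introns, presence-scored
expression over pollen and sporophytic tissues, a panel of fully
homozygous strains whose SNPs are drawn from class-specific gamma DFEs,
and diverged ortholog pairs evolved at class-specific dN/dS.

The generator and the DFE estimator share one implementation of the
selected-allele sampling distribution (:func:`pollenselect.dfe.selected_weights`),
so parameter-recovery tests close the loop exactly.  Allele frequencies
are drawn independently per site (no linkage), and at most one variant is
placed per codon, so multi-SNP codon masking never removes generator
signal; masking behaviour is exercised by dedicated fixtures instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dfe as _dfe
from .codons import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, position_degeneracy
from .io_formats import (
    GeneModel,
    VariantRecord,
    reverse_complement,
    write_expression_table,
    write_fasta,
    write_gff3,
    write_hit_table,
    write_variants_tsv,
)
from .diversity import SFSPair, fold_sfs

BASES = "ACGT"

POLLEN_TISSUES = (
    "pollen_uninucleate",
    "pollen_bicellular",
    "pollen_tricellular",
    "pollen_mature",
    "sperm_cell",
    "pollen_tube_a",
    "pollen_tube_b",
)
SPOROPHYTE_TISSUES = (
    "leaf",
    "root",
    "stem",
    "flower",
    "seed",
    "silique",
    "guard_cell",
    "xylem",
    "root_hair",
    "seedling",
)


@dataclass(frozen=True)
class ClassParams:
    """Selection regime of one gene class.

    ``dfe_mean_S`` is the mean scaled effect E[4*Ne*s] of new deleterious
    nonsynonymous mutations (0 = neutral); ``stop_gain_rate`` and
    ``indel_rate`` are expected numbers of segregating premature-stop
    alleles and frameshift indel sites per gene; ``omega`` and
    ``branch_dS`` set the interspecific divergence regime.
    """

    fraction: float
    dfe_shape: float = 0.3
    dfe_mean_S: float = 400.0
    stop_gain_rate: float = 2.0
    indel_rate: float = 0.5
    omega: float = 0.164
    branch_dS: float = 0.15


#: default class mix following the observed genome-wide proportions
#: (~21% silent, ~7.5% pollen-specific, ~26% sporophyte-specific); the
#: pollen class carries a 5x smaller mean scaled effect and 2x higher
#: deleterious-allele injection rates (its relaxed-selection regime)
DEFAULT_CLASSES: dict[str, ClassParams] = {
    "pollen_specific": ClassParams(
        fraction=0.075, dfe_mean_S=80.0, stop_gain_rate=4.0, indel_rate=1.0, omega=0.208
    ),
    "sporophyte_specific": ClassParams(fraction=0.264),
    "shared": ClassParams(fraction=0.454, omega=0.18),
    "silent": ClassParams(fraction=0.207, omega=0.3),
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 5
    genes_per_chromosome: int = 20
    n_strains: int = 80
    pollen_tissues: tuple = POLLEN_TISSUES
    sporophyte_tissues: tuple = SPOROPHYTE_TISSUES
    classes: Mapping[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    theta_site: float = 0.007  # scaled mutation rate per site (4 Ne mu)
    min_codons: int = 100
    max_codons: int = 400
    max_introns: int = 4
    min_intron: int = 60
    max_intron: int = 400
    intergenic_gap: int = 300
    chromosome_length: int | None = None  # None: sized to fit
    low_quality_rate: float = 0.02  # extra sub-threshold records emitted
    quality_threshold: float = 25.0

    def __post_init__(self):
        total = sum(c.fraction for c in self.classes.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class fractions sum to {total}, not 1")
        for name, c in self.classes.items():
            if c.dfe_shape <= 0 or c.dfe_mean_S < 0:
                raise ValueError(f"bad DFE parameters for class {name}")
        if self.theta_site <= 0:
            raise ValueError("theta_site must be positive")
        if len(self.sporophyte_tissues) < 5:
            raise ValueError("need at least five sporophytic tissues")

    def tissue_sides(self) -> dict[str, str]:
        sides = {t: "pollen" for t in self.pollen_tissues}
        sides.update({t: "sporophyte" for t in self.sporophyte_tissues})
        return sides


def null_config(**kwargs) -> SimulationConfig:
    """A configuration in which the pollen and sporophyte regimes are
    identical (every class comparison is null)."""
    base = ClassParams(fraction=0.5)
    classes = {
        "pollen_specific": replace(base, fraction=0.5),
        "sporophyte_specific": replace(base, fraction=0.5),
        "shared": replace(base, fraction=0.0),
        "silent": replace(base, fraction=0.0),
    }
    return SimulationConfig(classes=classes, **kwargs)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth: pd.DataFrame
    expression: pd.DataFrame
    variants: list[VariantRecord]
    strains: list[str]
    cds_a: dict[str, str]
    cds_b: dict[str, str]
    hits_ab: list
    hits_ba: list


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; no internal stop codons."""
    internal = rng.choice(
        [c for c in SENSE_CODONS if c != "ATG"] + ["ATG"], size=n_codons - 2
    )
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(internal) + str(stop)


def _class_counts(config: SimulationConfig, n_genes: int) -> list[str]:
    names = sorted(config.classes)
    counts = {k: int(math.floor(config.classes[k].fraction * n_genes)) for k in names}
    leftover = n_genes - sum(counts.values())
    for k in sorted(names, key=lambda k: -config.classes[k].fraction):
        if leftover == 0:
            break
        counts[k] += 1
        leftover -= 1
    out: list[str] = []
    for k in names:
        out.extend([k] * counts[k])
    return out


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Multi-chromosome genome, gene models with 0-4 introns, and the
    per-gene truth table (class and simulation parameters)."""
    rng = np.random.default_rng([config.seed, 1])
    n_genes = config.n_chromosomes * config.genes_per_chromosome
    classes = _class_counts(config, n_genes)
    rng.shuffle(classes)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    truth_rows = []
    g = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0  # 0-based length so far
        for _ in range(config.genes_per_chromosome):
            gene_id = f"g{g + 1:05d}"
            cls = classes[g]
            n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
            cds = _random_cds(rng, n_codons)
            n_introns = int(rng.integers(0, config.max_introns + 1))
            cut_points = sorted(
                rng.choice(np.arange(3, len(cds) - 3, 3), size=n_introns, replace=False)
            ) if n_introns else []
            gap = "".join(rng.choice(list(BASES), size=config.intergenic_gap))
            parts.append(gap)
            cursor += len(gap)
            gene_start = cursor + 1  # 1-based
            pieces = []
            intervals = []
            prev = 0
            pos = gene_start
            for cut in list(cut_points) + [len(cds)]:
                exon = cds[prev:cut]
                intervals.append((pos, pos + len(exon) - 1))
                pieces.append(exon)
                pos += len(exon)
                if cut != len(cds):
                    ilen = int(rng.integers(config.min_intron, config.max_intron + 1))
                    intron = "GT" + "".join(rng.choice(list(BASES), size=ilen - 4)) + "AG"
                    pieces.append(intron)
                    pos += ilen
                prev = cut
            strand = "+" if rng.random() < 0.5 else "-"
            locus = "".join(pieces)
            if strand == "-":
                locus = reverse_complement(locus)
                span = len(locus)
                intervals = [
                    (gene_start + span - 1 - (e - gene_start), gene_start + span - 1 - (s - gene_start))
                    for s, e in intervals
                ]
            parts.append(locus)
            cursor += len(locus)
            gene_end = cursor
            tx_intervals = sorted(intervals)
            if strand == "-":
                tx_intervals = tx_intervals[::-1]
            model = GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                strand=strand,
                cds_intervals=tuple(tx_intervals),
                gene_start=gene_start,
                gene_end=gene_end,
            )
            models.append(model)
            p = config.classes[cls]
            truth_rows.append(
                (gene_id, chrom, cls, n_codons, p.dfe_shape, p.dfe_mean_S,
                 p.stop_gain_rate, p.indel_rate, p.omega, p.branch_dS)
            )
            g += 1
        tail = "".join(rng.choice(list(BASES), size=config.intergenic_gap))
        parts.append(tail)
        seq = "".join(parts)
        if config.chromosome_length is not None:
            if len(seq) > config.chromosome_length:
                raise ValueError(
                    f"{chrom}: {len(seq)} bases of genes exceed chromosome "
                    f"length {config.chromosome_length}"
                )
            seq += "".join(rng.choice(list(BASES), size=config.chromosome_length - len(seq)))
        genome[chrom] = seq
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "chromosome", "life_stage_class", "n_codons",
                 "dfe_shape", "dfe_mean_S", "stop_gain_rate", "indel_rate",
                 "omega", "branch_dS"],
    )
    # sanity: every model round-trips to a clean ORF
    for m in models:
        cds = m.cds_sequence(genome[m.chromosome])
        assert len(cds) % 3 == 0 and cds[:3] == "ATG"
    return genome, models, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Presence-scored expression with class-consistent patterns.

    Pollen-specific genes are present (score >= 0.9) in a random subset of
    pollen tissues only; sporophyte-specific genes in 1..all sporophytic
    tissues (single-tissue genes restricted to one of guard cell, xylem or
    root hair); shared genes in both; silent genes nowhere.  Expression
    levels are log-normal, higher in pollen (median ~1,240 vs ~655).
    """
    rng = np.random.default_rng([config.seed, 2])
    single_types = [t for t in ("guard_cell", "xylem", "root_hair") if t in config.sporophyte_tissues]
    rows = []

    def present_level(mu: float) -> tuple[float, float]:
        return float(np.exp(rng.normal(mu, 0.8))), float(rng.uniform(0.9, 1.0))

    def absent_pair() -> tuple[float, float]:
        return float(np.exp(rng.normal(3.0, 1.0))), float(rng.uniform(0.0, 0.85))

    for gene_id, cls in zip(truth["gene_id"], truth["life_stage_class"]):
        pollen_on: set[str] = set()
        sporo_on: set[str] = set()
        if cls in ("pollen_specific", "shared"):
            k = int(rng.integers(1, len(config.pollen_tissues) + 1))
            pollen_on = set(rng.choice(config.pollen_tissues, size=k, replace=False))
        if cls in ("sporophyte_specific", "shared"):
            k = int(rng.integers(1, len(config.sporophyte_tissues) + 1))
            if k == 1 and single_types:
                sporo_on = {str(rng.choice(single_types))}
            else:
                sporo_on = set(rng.choice(config.sporophyte_tissues, size=k, replace=False))
        for t in config.pollen_tissues:
            lev, pres = present_level(7.12) if t in pollen_on else absent_pair()
            rows.append((gene_id, t, round(lev, 2), round(pres, 4)))
        for t in config.sporophyte_tissues:
            lev, pres = present_level(6.48) if t in sporo_on else absent_pair()
            rows.append((gene_id, t, round(lev, 2), round(pres, 4)))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "level", "presence"])


# ---------------------------------------------------------------------------
# strain variants
# ---------------------------------------------------------------------------


def _codon_site_classes(cds: str) -> list[tuple[int, list[int], list[int], list[tuple[int, str]]]]:
    """Per internal sense codon: (codon index, 4-fold positions, 0-fold
    positions, stop-gain (position, transcript alt) candidates)."""
    out = []
    n_codons = len(cds) // 3
    for ci in range(1, n_codons - 1):  # keep start and terminal codons intact
        codon = cds[ci * 3 : ci * 3 + 3]
        if codon in STOP_CODONS:
            continue
        four, zero, stopgain = [], [], []
        for p in range(3):
            deg = position_degeneracy(codon, p)
            if deg == "four_fold":
                four.append(p)
            elif deg == "zero_fold":
                zero.append(p)
            for b in BASES:
                if b != codon[p] and codon[:p] + b + codon[p + 1 :] in STOP_CODONS:
                    stopgain.append((p, b))
        out.append((ci, four, zero, stopgain))
    return out


def _draw_allele_count(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(rng.choice(np.arange(1, len(probs) + 1), p=probs))


def _nonsyn_alt(rng: np.random.Generator, codon: str, p: int) -> str | None:
    """A base change at a 0-fold position that is nonsynonymous and not a
    stop gain (stop gains are injected by their own process)."""
    alts = [
        b
        for b in BASES
        if b != codon[p] and codon[: p] + b + codon[p + 1 :] not in STOP_CODONS
    ]
    return str(rng.choice(alts)) if alts else None


def simulate_strain_variants(
    config: SimulationConfig,
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    truth: pd.DataFrame,
) -> tuple[list[VariantRecord], list[str]]:
    """Homozygous strain SNPs and indels drawn from class-specific regimes.

    Synonymous SNPs sit at 4-fold sites with allele counts from the
    neutral sample-frequency distribution (P(i) ∝ 1/i); nonsynonymous SNPs
    at 0-fold sites with counts from the class's gamma-DFE sampling
    distribution; premature-stop SNPs and frameshift indels are separate
    Poisson processes at the class rates.  Each codon carries at most one
    variant.
    """
    rng = np.random.default_rng([config.seed, 3])
    n = config.n_strains
    strains = [f"strain{k + 1:03d}" for k in range(n)]
    class_of = dict(zip(truth["gene_id"], truth["life_stage_class"]))
    i_range = np.arange(1, n)
    neutral_w = 1.0 / i_range
    neutral_p = neutral_w / neutral_w.sum()
    class_w: dict[str, np.ndarray] = {}
    class_probs: dict[str, np.ndarray] = {}
    for name, cp in config.classes.items():
        w = _dfe.gamma_weights(cp.dfe_shape, cp.dfe_mean_S, n)
        class_w[name] = w
        class_probs[name] = w / w.sum()
    records: list[VariantRecord] = []

    def qual() -> float:
        return float(np.round(rng.uniform(config.quality_threshold + 5, 60), 1))

    def emit_snp(model, cds, off, alt_tx, count):
        gpos = model.cds_to_genomic(off)
        ref_g = genome[model.chromosome][gpos - 1]
        alt_g = alt_tx if model.strand == "+" else reverse_complement(alt_tx)
        for s in rng.choice(strains, size=count, replace=False):
            records.append(VariantRecord(str(s), model.chromosome, gpos, ref_g, alt_g, qual()))
        if config.low_quality_rate > 0 and rng.random() < config.low_quality_rate:
            # sub-threshold noise record at another strain, filtered downstream
            s = str(rng.choice(strains))
            records.append(
                VariantRecord(s, model.chromosome, gpos, ref_g, alt_g,
                              float(np.round(rng.uniform(2, config.quality_threshold - 1), 1)))
            )

    for model in models:
        cls = class_of[model.gene_id]
        cp = config.classes[cls]
        cds = model.cds_sequence(genome[model.chromosome])
        codons = _codon_site_classes(cds)
        rng.shuffle(codons)
        pool = list(codons)
        L4 = sum(len(c[1]) for c in codons)
        L0 = sum(len(c[2]) for c in codons)
        sel_p = class_probs[cls]
        # expected segregating sites per frequency class, Poisson-drawn
        n_syn = rng.poisson(config.theta_site * L4 * neutral_w.sum())
        n_non = rng.poisson(config.theta_site * L0 * class_w[cls].sum())
        n_stop = rng.poisson(cp.stop_gain_rate)
        n_indel = rng.poisson(cp.indel_rate)

        def take(predicate):
            for k in range(len(pool)):
                if predicate(pool[k]):
                    return pool.pop(k)
            return None

        for _ in range(n_syn):
            c = take(lambda c: len(c[1]) > 0)
            if c is None:
                break
            ci, four, _, _ = c
            p = int(rng.choice(four))
            off = ci * 3 + p
            alt = str(rng.choice([b for b in BASES if b != cds[off]]))
            emit_snp(model, cds, off, alt, _draw_allele_count(rng, neutral_p))
        for _ in range(n_non):
            c = take(lambda c: len(c[2]) > 0)
            if c is None:
                break
            ci, _, zero, _ = c
            p = int(rng.choice(zero))
            off = ci * 3 + p
            codon = cds[ci * 3 : ci * 3 + 3]
            alt = _nonsyn_alt(rng, codon, p)
            if alt is None:
                continue
            emit_snp(model, cds, off, alt, _draw_allele_count(rng, sel_p))
        for _ in range(n_stop):
            c = take(lambda c: len(c[3]) > 0)
            if c is None:
                break
            ci, _, _, stopgain = c
            p, alt = stopgain[int(rng.integers(len(stopgain)))]
            emit_snp(model, cds, ci * 3 + p, alt, _draw_allele_count(rng, sel_p))
        for _ in range(n_indel):
            c = take(lambda c: True)
            if c is None:
                break
            ci = c[0]
            # need two CDS offsets that are genomically adjacent (left-anchored)
            placed = False
            for p in (0, 1):
                o1, o2 = ci * 3 + p, ci * 3 + p + 1
                g1, g2 = model.cds_to_genomic(o1), model.cds_to_genomic(o2)
                if abs(g1 - g2) != 1:
                    continue
                ga = min(g1, g2)
                chrom_seq = genome[model.chromosome]
                if rng.random() < 0.5:  # 1-nt deletion
                    ref, alt = chrom_seq[ga - 1 : ga + 1], chrom_seq[ga - 1]
                else:  # 1-nt insertion
                    ref = chrom_seq[ga - 1]
                    alt = ref + str(rng.choice(list(BASES)))
                count = _draw_allele_count(rng, sel_p)
                for s in rng.choice(strains, size=count, replace=False):
                    records.append(
                        VariantRecord(str(s), model.chromosome, ga, ref, alt, qual())
                    )
                placed = True
                break
            if not placed:
                continue
    records.sort(key=lambda r: (r.chromosome, r.position, r.strain_id, r.alt_allele))
    return records, strains


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def evolve_cds(
    cds: str, branch_dS: float, omega: float, rng: np.random.Generator
) -> str:
    """Evolve a CDS along one branch by a codon-level Markov jump process.

    Each single-base neighbour of the current codon is reached at rate
    dS/3 when synonymous and omega*dS/3 when nonsynonymous; changes to
    stop codons are forbidden.  With these rates the expected number of
    synonymous substitutions per Nei-Gojobori synonymous site over the
    branch equals ``branch_dS`` and nonsynonymous likewise at
    ``omega * branch_dS``, so the counting estimator applied to the output
    is asymptotically unbiased for (dS, omega).
    """
    mu_s = branch_dS / 3.0
    mu_n = omega * branch_dS / 3.0
    out = []
    for idx in range(0, len(cds), 3):
        codon = cds[idx : idx + 3]
        if codon in STOP_CODONS or any(b not in BASES for b in codon):
            out.append(codon)
            continue
        t = 0.0
        while True:
            neighbours = []
            rates = []
            aa = CODON_TO_AA[codon]
            for p in range(3):
                for b in BASES:
                    if b == codon[p]:
                        continue
                    alt = codon[:p] + b + codon[p + 1 :]
                    if alt in STOP_CODONS:
                        continue
                    neighbours.append(alt)
                    rates.append(mu_s if CODON_TO_AA[alt] == aa else mu_n)
            total = sum(rates)
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= 1.0:
                break
            codon = neighbours[int(rng.choice(len(rates), p=np.array(rates) / total))]
        out.append(codon)
    return "".join(out)


def simulate_divergence(
    config: SimulationConfig,
    genome: Mapping[str, str],
    models: Sequence[GeneModel],
    truth: pd.DataFrame,
) -> tuple[dict[str, str], dict[str, str], list, list]:
    """Ortholog CDS pairs diverged at class-specific (dS, omega), with a
    consistent mutual-best-hit protein table."""
    from .codons import translate
    from .io_formats import HitRecord

    rng = np.random.default_rng([config.seed, 4])
    class_of = dict(zip(truth["gene_id"], truth["life_stage_class"]))
    cds_a: dict[str, str] = {}
    cds_b: dict[str, str] = {}
    hits_ab = []
    hits_ba = []
    for model in models:
        cp = config.classes[class_of[model.gene_id]]
        ref = model.cds_sequence(genome[model.chromosome])
        div = evolve_cds(ref[:-3], cp.branch_dS, cp.omega, rng) + ref[-3:]
        a_id = model.gene_id
        b_id = f"{model.gene_id}_sp2"
        cds_a[a_id] = ref
        cds_b[b_id] = div
        prot_a = translate(ref[:-3])
        prot_b = translate(div[:-3])
        ident = 100.0 * sum(x == y for x, y in zip(prot_a, prot_b)) / len(prot_a)
        bits = round(2.0 * len(prot_a) * ident / 100.0, 1)
        hits_ab.append(HitRecord(a_id, b_id, round(ident, 2), len(prot_a), bits))
        hits_ba.append(HitRecord(b_id, a_id, round(ident, 2), len(prot_a), bits))
    return cds_a, cds_b, hits_ab, hits_ba


# ---------------------------------------------------------------------------
# SFS-level simulation (for estimator recovery at large L)
# ---------------------------------------------------------------------------


def simulate_sfs_pair(
    shape: float,
    mean_S: float,
    theta: float,
    n: int,
    L_n: float,
    L_s: float,
    rng: np.random.Generator,
    fold: bool = True,
    r: np.ndarray | None = None,
    div_ds: float = 0.0,
    adaptive_fraction: float = 0.0,
) -> SFSPair:
    """Poisson-sampled paired SFS directly from the DFE sampling model.

    When ``div_ds`` > 0, divergence counts are added: D_s ~ Poisson(L_s *
    div_ds) and D_n from the deleterious expectation inflated by the
    adaptive fraction a (D_n_total = D_n_deleterious / (1 - a)).
    """
    wn = _dfe.gamma_weights(shape, mean_S, n)
    ws = 1.0 / np.arange(1, n)
    if r is not None:
        wn = wn * r
        ws = ws * r
    if fold:
        wn, ws = fold_sfs(wn, n), fold_sfs(ws, n)
    sfs_n = rng.poisson(theta * L_n * wn).astype(float)
    sfs_s = rng.poisson(theta * L_s * ws).astype(float)
    D_n = D_s = 0.0
    if div_ds > 0:
        fit_like = _dfe.DFEFit(
            shape=shape, mean_S=mean_S, theta_hat=theta, r=np.ones(1),
            log_likelihood=0.0, n=n, folded=fold,
        )
        omega_na = _dfe.expected_nonadaptive_omega(fit_like)
        D_s = float(rng.poisson(L_s * div_ds))
        D_n = float(rng.poisson(L_n * div_ds * omega_na / (1.0 - adaptive_fraction)))
    return SFSPair(n=n, folded=fold, sfs_n=sfs_n, sfs_s=sfs_s, L_n=L_n, L_s=L_s, D_n=D_n, D_s=D_s)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """All synthetic inputs for one seeded run of the full pipeline."""
    genome, models, truth = simulate_genome(config)
    expression = simulate_expression(config, truth)
    variants, strains = simulate_strain_variants(config, genome, models, truth)
    cds_a, cds_b, hits_ab, hits_ba = simulate_divergence(config, genome, models, truth)
    return SyntheticDataset(
        config=config, genome=genome, models=models, truth=truth,
        expression=expression, variants=variants, strains=strains,
        cds_a=cds_a, cds_b=cds_b, hits_ab=hits_ab, hits_ba=hits_ba,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
        "expression": outdir / "expression.tsv",
        "variants": outdir / "variants.tsv",
        "cds_a": outdir / "cds_species_a.fasta",
        "cds_b": outdir / "cds_species_b.fasta",
        "hits_ab": outdir / "hits_ab.tsv",
        "hits_ba": outdir / "hits_ba.tsv",
    }
    write_fasta(ds.genome, paths["genome"])
    write_gff3(ds.models, paths["gff"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_expression_table(ds.expression, paths["expression"])
    write_variants_tsv(ds.variants, paths["variants"])
    write_fasta(ds.cds_a, paths["cds_a"])
    write_fasta(ds.cds_b, paths["cds_b"])
    write_hit_table(ds.hits_ab, paths["hits_ab"])
    write_hit_table(ds.hits_ba, paths["hits_ba"])
    return paths
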