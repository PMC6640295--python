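# pollenselect

Comparative population-genetic analysis of selection on **pollen-specific**
versus **sporophyte-specific** genes in a selfing plant.

Genes expressed only in the haploid gametophyte (pollen) experience a
different selection regime from genes expressed only in the diploid
sporophyte: haploid expression removes the masking of recessive alleles,
while high selfing rates erode both pollen competition and diploid
masking.  The package implements the full comparison pipeline used to ask
whether purifying selection is relaxed on pollen genes:

1. **Expression classing** — genes are called *present* in a tissue when
   their presence score is ≥ 0.9; genes reliably present only in pollen
   tissues are pollen-specific, only in sporophytic tissues
   sporophyte-specific.  Subgroups with expression limited to a single
   sporophyte cell type (guard cell, xylem, root hair) or spread over ≥ 5
   sporophytic tissues control for tissue specificity.
2. **Site-class diversity** — per-gene Watterson's θ = S / (a₍ₙ₋₁₎ L) and
   nucleotide diversity π at 0-fold (nonsynonymous) and 4-fold
   (synonymous) degenerate sites over a panel of homozygous inbred
   strains; codons carrying more than one SNP are masked.
3. **Deleterious alleles** — per-gene counts of unique premature-stop
   alternative alleles and the proportion of strains carrying a
   frameshift indel.
4. **Divergence** — reciprocal-best-hit orthologs (≥ 30 % identity over
   ≥ 150 aligned residues), protein-guided codon alignments, and
   Nei–Gojobori counting dN/dS with Jukes–Cantor correction
   (d = −¾ ln(1 − 4p/3)); pairs with dS > 2 are excluded.
5. **Distribution of fitness effects** — a gamma DFE over the scaled
   selection strength S = 4Nₑs is fitted by Poisson maximum likelihood to
   paired synonymous/nonsynonymous site-frequency spectra, with
   per-frequency-class nuisance multipliers r᷈ᵢ absorbing demography.
   Reported are the proportions of mutations in Nₑs bins
   ([0,2), [2,10), [10,100), [100,∞)), the adaptive proportion
   α = 1 − (D_s Lₙ / (Dₙ L_s)) · E[S/(eˢ−1)], and gene-bootstrap CIs.
6. **Covariate control** — Mann–Whitney U tests with Bonferroni
   correction, partial Spearman correlations, principal-component
   regression of each statistic on six genomic covariates (expression
   level, GC content, RSCU variance, gene length, average intron length,
   100-kb gene density) with jackknife predictor pruning, and an ANCOVA
   of the statistic on the best PC crossed with life stage, followed by
   five equal-count bins along the PC axis when slopes differ.

A fully seeded synthetic-data module generates every input the pipeline
consumes (genome FASTA, GFF3 gene models with introns, presence-scored
expression tables, strain variant calls drawn from class-specific gamma
DFEs, and ortholog pairs evolved at class-specific dN/dS), so the whole
analysis is testable end to end without external downloads.

## Worked example

Simulate 600 genes (300 per class, 80 strains) in which the pollen class
evolves under a relaxed regime — mean scaled effect E[4Nₑs] of new
nonsynonymous mutations 5× smaller, deleterious-allele injection rates 2×
higher — and run the full comparison (about 20 s):

```python
from dataclasses import replace
from pollenselect import pipeline, synthetic_data as sd

classes = {
    "pollen_specific": replace(sd.DEFAULT_CLASSES["pollen_specific"], fraction=0.5),
    "sporophyte_specific": replace(sd.DEFAULT_CLASSES["sporophyte_specific"], fraction=0.5),
    "shared": replace(sd.DEFAULT_CLASSES["shared"], fraction=0.0),
    "silent": replace(sd.DEFAULT_CLASSES["silent"], fraction=0.0),
}
cfg = sd.SimulationConfig(seed=31, n_chromosomes=5, genes_per_chromosome=120,
                          n_strains=80, classes=classes)
result = pipeline.analyze_dataset(sd.simulate_dataset(cfg))
for stat, c in result.comparisons.items():
    print(f"{stat:>24}  pollen={c.median_b:.4g}  sporophyte={c.median_a:.4g}  adj_p={c.adj_p:.2g}")
```

```
                   omega  pollen=0.1983  sporophyte=0.1512  adj_p=2.2e-17
                 theta_n  pollen=0.004295  sporophyte=0.0025  adj_p=2e-38
                    pi_n  pollen=0.003142  sporophyte=0.001719  adj_p=2.5e-30
   stop_allele_frequency  pollen=0.05  sporophyte=0.025  adj_p=3e-34
    frameshift_frequency  pollen=0.01796  sporophyte=1.735e-18  adj_p=1.6e-09
```

Every statistic is elevated in the pollen class: the counting-method dN/dS
medians recover the generating regimes (ω = 0.208 vs 0.164), θₙ and πₙ are
roughly 1.7× higher, and the premature-stop and frameshift frequencies
reflect the doubled injection rates (the sporophyte frameshift median is
zero up to floating-point round-off of the back-transform).  The adjusted
p-values are Bonferroni-corrected two-sided Mann–Whitney tests over the
five-statistic family.

A command-line interface mirrors the modules
(`pollenselect simulate|classify|covariates|consequences|diversity|divergence|dfe|compare`);
run any subcommand with `--help`.

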