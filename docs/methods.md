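# Methods

## Data model and conventions

Coordinates are 1-based inclusive genomic positions throughout (the GFF3
convention); VCF positions are used as-is.  CDS offsets are 0-based in
transcript orientation; for − strand genes alleles are
reverse-complemented at the mapping boundary and nowhere else.  Indels are
left-anchored with a shared first base, as in VCF.  Strains are fully
homozygous inbred lines: any non-reference genotype call is treated as a
homozygous carrier, and a per-strain tabular dialect
(`strain  chrom  pos  ref  alt  qual`) is accepted alongside VCF because
historical strain "genome matrix" releases predate uniform VCF.  Variant
calls below a phred threshold (default 25) are discarded on input;
records with no quality value fail the filter and are counted.

## Expression classing

A gene is *present* in a tissue when its presence score (a detection
reliability in [0,1], MAS5-style) reaches the threshold, default 0.9;
every other expression value is treated as zero.  Two pollen-tube columns
are merged by elementwise maximum of level and presence before classing.
The gene's expression level is the maximum level over present tissues —
the level that best represents its strongest phenotypic engagement.  The
four classes (pollen-specific, sporophyte-specific, shared, not
expressed) partition the gene set; shared genes are classified but
excluded from all two-group comparisons, which are built on exclusive
expression.  A gene present (score ≥ threshold) with a zero expression
level is treated as a data error and rejected, since presence asserts
reliable detection.

Tissue-specificity control groups: sporophyte genes present in exactly
one tissue drawn from a configurable cell-type list (guard cell, xylem,
root hair) and sporophyte genes present in at least five sporophytic
tissues.

## Diversity at 0-fold and 4-fold sites

Degeneracy is assigned from the reference codon under the standard
nuclear code: 4-fold positions (all three changes synonymous) proxy
synonymous sites, 0-fold positions (no synonymous change) proxy
nonsynonymous sites.  Codons with more than one polymorphic position in
the panel are masked entirely, as are codons containing ambiguity codes.
A site enters the spectra only when every strain has a call there and at
most one alternative allele segregates; excluded sites are removed from
the site tally L.  Per gene, θ = S/(a₍ₙ₋₁₎L) with a₍ₙ₋₁₎ = Σ 1/i, and π is
computed from the spectrum as Σᵢ i(n−i)·sfs[i] / C(n,2) / L (the weight
i(n−i) is symmetric, so the same formula serves folded spectra).  Folded
spectra (minor-allele counts) are the default DFE input because no
outgroup polarisation is assumed.

## Deleterious alleles

Premature stops are scored from SNPs only: within a strain, all SNPs of a
codon are applied jointly, and a codon before the reference terminal stop
that becomes a stop codon contributes an allele keyed by its causal
(CDS position, alternative base) pairs; the per-gene statistic is the
number of unique such alleles, reported raw and divided by the strain
count so means are comparable across panels of different size.  A change
in the terminal stop codon is a stop-loss and is ignored.  Frameshifts
are scored from indels only: a strain counts once if it carries at least
one CDS indel whose length change is not a multiple of 3.  Keying stop
alleles on position+base (rather than on mutant haplotypes) is a declared
choice; the two coincide except for multi-SNP codons.

## Counting dN/dS

Nei–Gojobori (1986) counting with equal-weight path averaging: each
codon's synonymous site count is the sum over positions of the fraction
of one-step changes that are synonymous (changes to stops count as
nonsynonymous); observed codon differences are resolved by averaging the
synonymous/nonsynonymous step counts over all minimal substitution paths.
Columns with a gap, stop codon, or ambiguity in either sequence are
dropped pairwise.  Proportions are Jukes–Cantor corrected,
d = −¾ ln(1 − 4p/3); pairs are excluded when the correction is undefined
(p ≥ ¾) or dS exceeds a ceiling (default 2).  ω for dS = 0 with dN > 0 is
reported as +∞ and excluded from rank tests; identical sequences give ω
undefined.  Orthology is established by reciprocal best BLAST hits with
bit-score ranking (ties broken by higher identity, then lexicographic
subject id) at ≥ 30 % identity over ≥ 150 aligned residues.  The counting
method stands in for maximum-likelihood codon models deliberately: it is
self-contained, fast at desk scale, and exactly checkable against a
path-enumeration oracle; the analysis surface is the group-level
contrast, not per-gene point estimates.

## Gamma DFE from paired spectra

Scaled selection is parameterised internally as S = 4Nₑs (deleterious
magnitude; the model has no beneficial mass).  The sojourn density of a
deleterious mutation at frequency x is H(x;S) =
(1−e^{S(1−x)}) / [x(1−x)(1−e^{S})], with neutral limit 1/x; binomial
sampling of n genomes gives per-class weights wᵢ(S) = ∫ C(n,i) xⁱ(1−x)ⁿ⁻ⁱ
H(x;S) dx, and the expected nonsynonymous count in class i is
θ·Lₙ·rᵢ·E_Γ[wᵢ(S)] with synonymous counts at S=0.  The rᵢ (r₁ ≡ 1) are
shared nuisance multipliers absorbing demography and ascertainment.

Numerics: for fixed (shape b, mean S̄) the conditional maxima of θ and r
under the Poisson likelihood are closed-form, so fitting is a
two-parameter profile search (Nelder–Mead on the log scale from five
dispersed starts; a single warm start inside the bootstrap).  wᵢ(S) is
computed by Gauss–Legendre quadrature with an interval split at the
x ≈ 1/S boundary layer, stabilised via
e^{−Sx}·expm1(−S(1−x))/expm1(−S); for speed these weights are
precomputed once per sample size on a 512-point log-S grid (10⁻⁴…3×10⁸)
and interpolated log-log linearly (the weights are smooth, asymptotically
power-law in S; interpolation reproduces direct quadrature to ~10⁻⁴
relative, well below sampling noise).  The gamma expectation uses 32
Gauss–Legendre nodes in CDF space.  Parameter bounds are enforced by
penalty; estimates at the bounds are flagged.

Bin proportions are gamma CDF differences on the Nₑs = S/4 scale, default
edges (0, 2, 10, 100, ∞), reconciling the "effectively neutral" (< 2) and
"strongly deleterious" (> 10) landmarks with a four-bin summary.  The
adaptive proportion is α = 1 − (D_s Lₙ)/(Dₙ L_s) · E_Γ[S/(eˢ−1)], the
expectation being the fixation probability of deleterious mutations
relative to neutral.  Bootstrap intervals resample genes with
replacement, sum spectra, site tallies and divergence counts, refit
warm-started, and take 2.5/97.5 percentiles; replicate failures are
recorded and excluded, with a warning above 5 %.

## Covariates and group comparison

The six covariates are the gene's expression level, GC content
(percent G+C among unambiguous bases, computed over the unspliced genomic
span by default — configurable to the CDS — matching the gene-span scope
of the length covariates), within-gene RSCU variance (RSCU = codon count
× family size / family total, stop codons excluded, unused families
omitted, single-codon amino acids included at RSCU ≡ 1), gene length
(genomic span), average intron length (mean CDS-interval gap, 0 when
intronless), and gene density (genes in the fixed half-open 100-kb window
containing the gene start).

Group tests are two-sided Mann–Whitney U with Bonferroni correction over
the declared family (the five statistics, or the five PC bins).  Partial
Spearman correlations are Pearson correlations of rank-regression
residuals with t-based p on n−2−k degrees of freedom.

PC regression: all variables are log-transformed (offset 10⁻⁴ added to
gene length and average intron length for zero values; a zero dependent
is offset by half its smallest positive observed value — explicit and
monotone).  Predictors are standardised; the dependent is regressed on
each principal component; the component explaining the most dependent
variance (squared correlation × 100) is the ANCOVA axis.  Predictor
significance uses a leave-one-observation-out jackknife of the
loading-weighted regression coefficients aggregated over all components
(βₚ = Σⱼ slopeⱼ·loadingₚⱼ — invariant to component sign and ordering, and
equal to the full PCR coefficient vector, the quantity the classical
`jack.test` examines); a single selected component cannot separate
predictors that load symmetrically, which is why the aggregate is used.
Nonsignificant predictors (p ≥ 0.05) are removed together and the model
refit until all survivors are significant; the history is recorded.  When
every predictor is pruned there is nothing to control for: the rank test
is still reported and the ANCOVA fields stay empty.

ANCOVA fits dependent ~ PC × group on the log scale; when the slope
interaction is significant (p < 0.05) the comparison is summarised within
five equal-count bins along the pooled PC axis (rank-based binning, sizes
within 1 of each other; "equal bins" means 20 % quantiles).  Bin medians
back-transform exactly through the monotone log map; back-transformed bin
means are geometric means.

## Synthetic data: what it emulates and what it does not

The generator produces the study's input structure under known truth:
five chromosomes of protein-coding genes (random sense codons between ATG
and a stop, 0–4 introns of 60–400 nt, random strand), presence-scored
expression over 7 pollen-side and 10 sporophytic tissues with log-normal
levels (higher in pollen, medians ≈ 1,240 vs ≈ 655), a homozygous strain
panel, and diverged ortholog pairs.  Default class fractions follow the
observed genome-wide proportions (≈ 21 % silent, 7.5 % pollen-specific,
26 % sporophyte-specific, the rest shared); the default per-site scaled
mutation rate θ = 0.007 is a typical selfing-crucifer synonymous
diversity.  The pollen class's relaxed regime is built in as a 5× smaller
mean scaled effect (E[4Nₑs] = 80 vs 400, shape 0.3) and 2× higher
premature-stop and frameshift injection rates (4 vs 2 and 1 vs 0.5
expected events per gene), sized so deleterious-allele frequencies land
in the few-percent range on an 80-strain panel.  Divergence regimes are
ω = 0.208 (pollen) vs 0.164 (sporophyte) at branch dS = 0.15 — the
pollen-elevated contrast at realistic divergence depth.

Synonymous SNPs land on 4-fold sites with allele counts drawn from the
neutral sampling distribution P(i) ∝ 1/i; nonsynonymous SNPs land on
0-fold sites with counts drawn from the same gamma-DFE weights the
estimator integrates — one shared implementation, so parameter-recovery
tests close the loop exactly.  Premature-stop SNPs and frameshift indels
are separate Poisson processes, giving direct control of the consequence
module's effect sizes.  Sites are independent (no linkage, no
genealogy): every statistic analysed here is site-wise, so coalescent
correlation structure would change variances but not expectations.  At
most one variant is placed per codon, so multi-SNP masking removes no
generator signal (masking is exercised by dedicated fixtures).  Ortholog
divergence runs a codon-level Markov jump process with per-neighbour
rates dS/3 (synonymous) and ω·dS/3 (nonsynonymous), stops forbidden —
multiple hits arise naturally, which is what the Jukes–Cantor correction
of the estimator assumes.  Real data differ in ways the generator does
not model: linked selection, recombination and demography distort
spectra jointly rather than through free rᵢ multipliers; expression is
correlated with sequence composition; and genes vary in mutation rate.
Passing tests therefore demonstrate estimator correctness and pipeline
discrimination under the stated model, not robustness to those
real-data complications.

## Problem sizes

The test suite and acceptance script run the end-to-end comparison at
600 genes (300 per class) × 80 strains, DFE recovery at n = 80 with
Lₙ = 2×10⁶ / L_s = 5×10⁵ sites over 20 replicates, bootstrap coverage at
B = 200 over 20 datasets of 120 genes, dN/dS recovery on 10,000-codon
alignments, and null calibration over 50 seeds of a 40-gene, 24-strain
panel — sizes at which every Monte-Carlo tolerance above is comfortably
resolved on a single CPU in a few minutes.

## Known limitations

* The DFE model has no beneficial mutation class; α is inferred from
  divergence counts only, and demographic distortions beyond the rᵢ
  multipliers (e.g. recent selfing-driven Nₑ change) bias α, as expected
  for this model family.
* Counting dN/dS saturates sooner than ML codon models; pairs beyond
  dS = 2 (or p ≥ ¾) are excluded rather than estimated.
* Premature-stop uniqueness keyed on position+base undercounts distinct
  mutant haplotypes in multi-SNP codons; both conventions coincide on
  the synthetic data.
* Heterozygous calls, splice-site disruption, start-loss and stop-loss
  consequences, and phased genotypes are out of scope.
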