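# Methods

This note documents the models, estimators, numerical choices and
limitations behind `balnoise`, in the spirit of a package methods
appendix.  Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Diversity statistics and the balancing scan

Nucleotide diversity is computed in its frequency form,
π = n/(n−1) · Σᵢ 2pᵢqᵢ over segregating sites, which equals the mean
pairwise Hamming distance over all C(n,2) haplotypes (this identity is
property-tested).  Watterson's estimator is θs = S/aₙ with
aₙ = Σ_{i<n} 1/i.  Tajima's *D* = (π − θs)/√(e₁S + e₂S(S−1)) uses the
standard 1989 normalizing constants; *D* is flagged undefined (not
silently NaN) when S = 0 or the variance vanishes.  Scan windows are
5 kb, half-open, centered on the focal SNP ([pos − 2500, pos + 2500));
all internal coordinates are 0-based half-open, converted at the VCF
boundary.

Haplogroup π profiles partition haplotypes by the focal-SNP allele and
report, in 500-bp sliding windows (default step 100 bp), the mean
pairwise difference count between classes and the pair-count-weighted
mean within classes.  An old balanced polymorphism shows
between > within at the focal window.

Fst is the heterozygosity form 1 − Hs/Ht with Hs the (weighted) mean
subpopulation 2pq and Ht = 2p̄q̄; it is undefined for globally
monomorphic input.  LD r² is the squared dosage correlation, which for
phased haploid input coincides with the haplotype-frequency
D²/(p₁q₁p₂q₂) (oracle-tested).  The Hardy–Weinberg test is the exact
conditional test (sum of heterozygote-count probabilities no larger
than the observed one, conditioning on allele counts), verified against
full enumeration with exact rational arithmetic up to n = 50.

## The ML-HKA test

The HKA comparison of polymorphism to divergence uses a Poisson
random-field likelihood: for locus *i* with sample size nᵢ,
Sᵢ ~ Poisson(kᵢθᵢa_{nᵢ}) and Dvᵢ ~ Poisson(θᵢ(t + 1)), where the +1
absorbs ancestral polymorphism carried into divergence, and kᵢ = k at
the single focal locus (k multiplies polymorphism only — a k-fold
elevation of diversity).  The per-locus θᵢ profile out analytically,
leaving a 1-D (neutral, k ≡ 1) or 2-D (selection) optimization in
log-parameters from a coarse multi-start grid; the LRT 2ΔlogL is
referred to χ²(1).  This is a maximum-likelihood reimplementation of
the published approach whose exact likelihood is not printed; it is
ML-only (no MCMC chain), and its null calibration (k̂ ≈ 1,
approximately uniform p) and power (≥80% at five-fold polymorphism
inflation against 99 reference loci) are checked by simulation.

## Artifact filters and classification

Filters flag rather than drop, so every exclusion is auditable: (i)
high-depth proximity — the 50-kb flank intersects a region in the top
0.1% of the mapping-depth track; (ii) mappability — any 50-mer
overlapping the site intersects a non-unique region (the track supplies
non-unique intervals; genome-scale k-mer indexing is out of scope);
(iii) segmental duplications ≥1 kb and ≥90% identity containing the
site; (iv) MAF < 1%; (v) exact-HWE p below 0.05 after Bonferroni
correction across all SNPs entering the test (post-MAF, matching the
workflow order).  Classification uses empirical quantiles
(numpy's default linear interpolation): balanced = statistic ≥ the
99th percentile with boundary ties included on the balanced side;
control = [10th, 90th).  The desk-scale workflow default is
(90th; [10th, 80th)) because the synthetic dataset has ~70 eligible
SNPs.  Balanced SNPs with a nonsynonymous partner within 500 kb at
r² > 0.9 and strictly higher *D* are excluded as putative hitch-hikers.

## Enrichment, motifs, imbalance, association

Overlap enrichment is the ratio of overlap *rates* of balanced vs
control sets (the sets differ ~80-fold in size, so raw-count ratios are
also emitted but not used as the score); a SNP counts once per track
however many intervals it hits; zero control overlap leaves the score
undefined rather than pseudocounted.  Gene-set testing is the one-sided
hypergeometric upper tail per term with Benjamini–Hochberg correction;
the default background is the gene universe of the enhancer–promoter
map.

PFMs become log-odds PWMs against the background model with a
pseudocount of 0.25 per cell.  Scores are quantized on a 10⁻³ lattice,
making the null distribution of a background word exactly computable by
convolution; the p-value threshold is the smallest achievable score
with tail probability ≤ p.  Because the discrete null is granular, a
weak or short motif may admit no threshold at p = 10⁻⁴, in which case
the scanner returns no hits — identical to the enumeration definition
(verified exhaustively at width 8).  Scanning covers every window of
both strands of the ±20-bp allele flanks, skipping windows with
ambiguity codes; the motif-divergence score is
(#allele-specific TFs)/(#common TFs), undefined when no TF binds both
alleles.

Allelic imbalance is |log2(ref/alt)| at heterozygous sites with depth
≥ 10; a zero count on either allele excludes the site with a reason
(it is itself extreme imbalance, reported separately rather than
pseudocounted), and magnitudes are median-normalized against the
control set per cell type.  Genotype–expression association is OLS on
additive dosage (no covariates by default), reporting R², the
regression p and its Bonferroni adjustment over all SNP–gene pairs
tested study-wide.

## The transcriptional-noise model

The promoter model yields f(T) = R(1+sT)/(1+R+(1+sR)T) with
τ = (1+R)/(1+sR), fold change φ = (R+1)/(R+1/s) and basal level
f(0) = R/(1+R); the three algebraic forms of f are cross-checked to
10⁻¹². The TF level is gamma-distributed, T ~ Γ(a, b), placed directly
on the K₂-scaled variable because K₂ and b are not separately
identifiable (rescaling a gamma variate stays in the family).
Heterozygote: g_λ(T) = [f(T) + f(T/λ)]/2 — both alleles see the *same*
TF draw but with dissociation constants K₂ and λK₂.  Homozygote: both
alleles at λ̄K₂, with λ̄ solved from ⟨f(T/λ̄)⟩ = ⟨g_λ(T)⟩ by bracketed
root-finding on the monotone mean map (residual < 10⁻¹⁰).

Ensemble means and variances are computed by 600-node Gauss–Legendre
quadrature on the probability transform u ↦ Γ⁻¹(u), which is smooth and
bounded for the bounded integrands involved (f ≤ 1); quadrature is
cross-checked against 10⁷-sample Monte Carlo within 3 SE.

The protein-noise decomposition is the additive form

η_p² = 1/⟨p⟩ + (1/⟨m⟩)/(1+γm/γp) + 1/⟨m⟩ + η_g²,

with steady-state means ⟨m⟩ = (αm/γm)⟨g⟩ and ⟨p⟩ = (αp/γp)⟨m⟩ and the
extrinsic term η_g² = Var(g)/⟨g⟩².  **Domain of validity**: this form
carries the full mRNA Poisson CV² (1/⟨m⟩) in addition to the attenuated
propagation term; the exact stationary solution of the two-stage
birth–death master equation contains only the attenuated term, so the
additive form overstates total noise by ≈1/⟨m⟩.  The model is therefore
quantitatively accurate for highly expressed genes, where extrinsic
noise dominates and 1/⟨m⟩ is negligible — precisely the regime the
noise-buffering argument addresses (low-expression genes are
intrinsic-noise-dominated and are excluded from the empirical CV²
analysis anyway).  The stochastic cross-check accordingly uses
parameter sets with ⟨m⟩ ≳ 5000 where the extra term is ~1% of the
total, and a chemical-Langevin integrator (Euler–Maruyama, dt = 0.01 in
units of the mRNA lifetime, 80 lifetimes of relaxation), whose first
two moments are exact for this linear reaction system.

Mean matching cancels every mean-dependent term, so
Δη² = η_p²[hom] − η_p²[het] = (Var f_λ̄ − Var g_λ)/⟨g⟩²: the
heterozygote's rate, an average of two differently-scaled copies of f,
is a flatter function of the fluctuating TF level, hence Δη² ≥ 0 with
equality at λ = 1 (checked to 10⁻¹⁰), growing as λ departs from 1, for
both activator and repressor parameterizations.  Grid defaults
(R = 1; s = 4 or 0.25; αm, αp, γm, γp in mRNA-lifetime units) are
package choices within plausible in-vivo ranges, not published values.

## Synthetic data: what it emulates and what it does not

The haplotype generator is Hudson's neutral coalescent (no
recombination, infinite sites, time in units of 2N generations;
mutations Poisson at θ/2 per unit branch length, positions uniform).
It is validated against msprime (mean S, mean π, mean *D* agree within
Monte-Carlo error) and against the theoretical E[S] = θaₙ, E[π] = θ.
The balanced generator is a two-class structured coalescent: lineages
coalesce only within their allelic class until `class_split_time`,
then freely; the focal SNP (frequency 0.5 by default, a knob) is the
class indicator at the window center.  **Study conditions**: defaults
are n = 100 haplotypes, 5-kb windows, θ = 5 per window (human-like
0.001/bp), and split time 6.0 — about three times the typical neutral
TMRCA, i.e., an unambiguously old balanced polymorphism; this age was
calibrated once so that planted loci meet the generator's design
requirement of ≥5-fold enrichment in the top 1% of *D* (an age of 4
gives ~4-fold, 6 gives ~12-fold).  Not emulated: recombination,
demography, sequencing error, reference bias, genome-scale LD — so
passing tests demonstrate correctness of the statistics and the
planted-signal logic, not robustness to those real-data complications.

Read counts at heterozygous sites are Poisson-depth binomial thinning
with allele-bias odds b/(1+b).  Single-cell expression is gamma-mixed
Poisson per the noise model (one shared TF draw per cell; an
`uncoupled` knob gives the heterozygote two independent draws, a
stronger-buffering variant).  Single-cell ATAC counts are Poisson with
gamma per-cell depth heterogeneity and a per-(cell, group) gamma
extrinsic factor; the chromatin-variability statistic is the SD across
cells of (observed − expected)/√expected with expected = cell depth ×
group accessibility fraction, and its uncertainty is a seeded cell
bootstrap.  Because the expected counts are normalized by the realized
total depth, the statistic is only attributable to a group that is a
small fraction of the peak catalog; simulated designs therefore include
a large zero-extrinsic background group, as the genome-wide catalog
provides in real data.

The fixture dataset plants ten failures per artifact filter (with a
decoy segdup below the identity threshold that must not flag), seven
old balanced clusters among 63 neutral ones, a ~3× enriched DHS track,
four common plus four allele-specific PFMs at one SNP (divergence score
exactly 1.0 — the allele-specific consensus concentrates its
information at the SNP position so a mismatch there, and only there,
falls below the 10⁻⁴ threshold), a two-fold allele read bias at
balanced SNPs, one dosage-driven eQTL gene and one gene-set term
collecting the balanced targets.  Haplotypes are shuffled before being
paired into diploids so genotypes satisfy random mating (the raw
two-class matrix would otherwise fail HWE at the planted loci en
masse).

## Numerical and determinism choices

Every generator takes a seed or Generator; fixed seed ⇒ byte-identical
outputs, and the end-to-end pipeline writes TSVs with fixed float
formatting so reruns are byte-identical.  Quantile type, tie rules,
half-open bin and window conventions are stated above and tested at
their boundaries.  Problem sizes in the test suite (e.g., 50,000 + 500
scan loci, 2,000 neutral replicates, 200-500 HKA fits, 10⁷-sample MC,
4,000 Langevin cells) are chosen to resolve each claim's signal well
beyond its Monte-Carlo error on a single CPU.

## Known limitations

* The HKA likelihood is the standard Poisson approximation, not the
  original software's exact likelihood; k̂ is slightly
  upward-dispersed at small locus counts.
* The noise decomposition is quantitatively valid only for highly
  expressed genes (see above); Δη² sign and monotonicity claims are
  grid-verified, not proven analytically here.
* No recombination anywhere: haplogroup profiles decay with distance in
  real data but not in the simulator.
* The LD estimator on unphased dosages is the composite correlation;
  haplotype-level r² is obtained only when phased input is supplied.
* "Noise strength" is σ²/μ (the conventional Fano-like measure); the
  correlation with selection statistics uses log noise strength by
  default (Spearman optional).
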