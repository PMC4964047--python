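# balnoise

Detection of balanced *cis*-regulatory SNPs and modeling of the
expression-noise advantage of regulatory heterozygosity.

## The scientific problem

Balancing selection maintains both alleles of a polymorphism at
intermediate frequency.  When it acts on *cis*-regulatory sequence
(transcription-factor footprints, enhancers), the classical signatures
are an excess of intermediate-frequency variation around the selected
site — positive Tajima's *D*, an elevated polymorphism-to-divergence
ratio (HKA selection parameter *k* > 1), low between-population *F*st —
and deep divergence between the two allelic haplogroups.  One candidate
benefit of regulatory heterozygosity is *noise buffering*: if the two
alleles bind partially different regulator pools, fluctuations in those
regulators average out across alleles, so a heterozygote's expression is
more homogeneous across cells than a mean-matched homozygote's.

`balnoise` is a toolkit for this whole analysis arc, aimed at population
geneticists and regulatory genomicists:

* **scan** — Tajima's *D* over 5-kb windows centered on footprint SNPs,
  haplogroup π profiles, *F*st = 1 − *H*s/*H*t, LD *r*², an exact
  Hardy–Weinberg test, and a maximum-likelihood HKA test with a
  χ²(1) likelihood-ratio test (`popgen`, `hka`);
* **filter & classify** — artifact filters (mapping-depth flank,
  50-mer mappability, segmental duplications, MAF ≥ 1%,
  Bonferroni-adjusted HWE), top-1%-of-*D* balanced set vs middle-80%
  control set, and exclusion of regulatory SNPs hitch-hiking on linked
  (r² > 0.9, <500 kb) nonsynonymous variants (`pipeline`);
* **characterize** — cell-type/TF overlap enrichment, target-gene
  mapping through enhancer–promoter links, hypergeometric gene-set
  tests with BH correction, allelic read-count imbalance, and PWM
  scanning with exact dynamic-programming p-value thresholds for
  motif-divergence scores (`enrichment`, `allelic`, `motifs`);
* **associate** — genotype dosage vs expression OLS (R², Bonferroni),
  tag-SNP lookup, transcriptional responsiveness (`association`);
* **model** — the equilibrium promoter-occupancy model of
  transcriptional noise (below) (`noise_model`);
* **measure** — single-cell CV²–mean fits, noise strength σ²/μ, and
  cell-to-cell chromatin-accessibility variability with cell bootstrap
  (`singlecell`);
* **simulate** — coalescent and count-model generators for every input,
  with planted truths, so the entire pipeline runs and is tested
  without any external data (`simulate`, `fixtures`).

## The noise model

With polymerase level *R* (scaled by its promoter dissociation constant)
and TF level *T* (scaled by the TF–DNA dissociation constant *K*₂), the
equilibrium transcription rate is

```
f(T) = R(1 + sT) / (1 + R + (1 + sR)T),     s = K1/K3
```

(*s* > 1 activator, *s* < 1 repressor).  A heterozygote whose alleles
bind the TF with constants *K*₂ and λ*K*₂ transcribes at
g_λ(T) = [f(T) + f(T/λ)]/2; the mean-matched homozygote carries λ̄*K*₂
on both alleles, with λ̄ solving ⟨f(T/λ̄)⟩ = ⟨g_λ(T)⟩ over the cell
ensemble T ~ Γ(a, b).  The stationary protein noise decomposes as

```
eta_p^2 = 1/<p> + (1/<m>)/(1 + gamma_m/gamma_p) + 1/<m> + eta_g^2
```

and mean matching cancels everything except the extrinsic term
η_g² = Var(g)/⟨g⟩², so

```
delta_eta2 = eta_p^2[hom] - eta_p^2[het] >= 0,   with equality iff lambda = 1.
```

Averaging two differently-scaled copies of *f* flattens the response to
TF fluctuations — heterozygotes buffer extrinsic noise.

## Worked example

```python
from balnoise.noise_model import NoiseModelParams, delta_eta2

rows = delta_eta2(NoiseModelParams(s=4.0), lam_grid=(2.0, 10.0), a_grid=(1.0,))
for r in rows:
    print(f"lam={r.lam:<5g} lam_bar={r.lam_bar:.4f} "
          f"eta2_het={r.eta2_het:.5f} eta2_hom={r.eta2_hom:.5f} "
          f"delta={r.delta_eta2:.5f}")
```

prints

```
lam=2     lam_bar=1.4197 eta2_het=0.01974 eta2_hom=0.02011 delta=0.00037
lam=10    lam_bar=2.8626 eta2_het=0.01675 eta2_hom=0.01982 delta=0.00307
```

With a two-fold allele discrepancy (λ = 2) the mean-matched homozygote
(λ̄ ≈ 1.42 on both alleles) is already noisier than the heterozygote
(Δη² ≈ 4·10⁻⁴); at λ = 10 the gap grows to Δη² ≈ 0.003 — about 18% of
the heterozygote's total noise.  The same machinery drives the
end-to-end synthetic scan:

```
balnoise simulate --out data/ --seed 1
balnoise pipeline --data data/ --out results/
```

which reports the planted artifact-filter failures, the ~3× enriched
DHS track, the allele-specific motif set (divergence score 1.0) and the
planted eQTL in `results/*.tsv`.

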