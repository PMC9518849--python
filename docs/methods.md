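# Methods

This note documents the models behind `laaabench`, the choices made where
the design was open, and what the synthetic data does and does not capture.

## Genotype and local-ancestry simulation

The cohort generator produces the two properties that the association
benchmark actually exercises — differentiated ancestral allele frequencies
and admixture LD with exact truth labels — without a coalescent simulation.

**Allele frequencies.** Each site has a shared ancestral frequency
p ~ Uniform(0.05, 0.95). Source-population frequencies follow the
Balding–Nichols model, p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so
E[p_k] = p and Var[p_k] = F_k·p(1−p). Default differentiation values are
F = 0.15 (NAMA/Khoe-San), 0.08 (LWK, MSL), 0.12 (GBR, GIH), 0.14 (CHB);
the ordering reflects the strong divergence of Khoe-San lineages, but the
exact values are tuning constants, configurable per preset. Reference
haplotypes are independent Bernoulli(p_k) draws per site: there is **no
background LD** within source populations (see Limitations).

**Tract mosaics.** Admixture pulses are applied newest first. The most
recent pulse (age g₁ generations) lays recombination breakpoints as a
Poisson process at rate g₁ per Morgan and labels each segment with one of
its incoming sources (probability = the pulse-time admixture fraction) or
leaves it as background; each older pulse adds breakpoints inside the
remaining background at the rate increment g₂ − g₁ and labels the same
way; background surviving the oldest pulse takes the base ancestry.
Pulse-time fractions are chosen so the marginal expected ancestry
proportions equal the preset's declared final proportions (for the
three-way preset, the older east-African pulse uses 0.10/0.85 ≈ 0.1176 so
that the later 0.15 European pulse thins it to a 0.10 marginal); the
preset validates this identity at construction. For a single founding
pulse this reduces to one Poisson layer whose segment labels are drawn
from the final proportions. Under that single-pulse process, interior
tracts of ancestry k are exponential with mean 1/(g(1−π_k)) Morgans and
the correlation of same-haplotype ancestry indicators decays as e^(−g·d);
both are property-tested (on a long chromosome, since finite chromosomes
censor long tracts).

**Presets.** `nama3`: sources LWK/GBR/NAMA with final proportions
0.10/0.15/0.75, pulses at g = 80 (east-African, ≈2000 years at 25
years/generation) and g = 10 (European, ≈250 years). `sac5`: sources
CHB/GBR/MSL/NAMA/GIH with proportions 0.100/0.175/0.250/0.350/0.125 and a
single founding pulse at g = 16. Desk-scale defaults: 500 admixed
individuals, 200 reference individuals per source, 10,000 sites evenly
spaced on four chromosomes of 50 Mb (0.5 Morgan each, uniform 1 cM/Mb);
all sizes and a plink-style non-uniform genetic map are configurable.
Admixed haplotypes copy alleles from a uniformly drawn reference haplotype
per tract, so genotypes and truth labels agree site-for-site by
construction.

**Coordinates and formats.** Internally 0-based half-open bp; VCF output
is 1-based with phased GT (REF = internal allele 1). Local ancestry
round-trips through an RFMix2-style `.msp.tsv` whose rows are maximal
intervals with constant labels across all haplotypes.

## Observed ("inferred") ancestry

Real analyses see local-ancestry-inference (LAI) output, not truth. The
corruption model partitions each haplotype into error blocks (Poisson,
mean 0.1 Morgan, overlaid on true tract boundaries so each block has one
true ancestry k) and relabels a whole block with probability 1 − a_k,
choosing the wrong label proportionally to the other ancestries'
cohort-wide proportions — errors are switch-like and gravitate toward
majority components, as LAI errors do. Default target accuracies are the
per-ancestry values emulated for the two presets (three-way: LWK 0.761,
GBR 0.884, NAMA 0.853; five-way: CHB 0.831, GBR 0.892, MSL 0.846, NAMA
0.847, GIH 0.854), giving proportion-weighted overall accuracies of
≈ 0.849 and ≈ 0.854. Global ancestry P is always the genome-wide mean of
whichever local-ancestry matrix (true or observed) the condition uses.
Allele/label pairing per haplotype is preserved, so interaction dosages
stay internally consistent under corruption.

## Phenotype simulation

Phenotypes are sums of six components, each scaled to a fixed share of the
total variance: variant (allelic dosage at 10 causal SNPs, standard-normal
weights), local ancestry (ancestry-of-interest dosage at the same SNPs),
interaction (ancestry-specific allelic dosage), population structure (a
zero-mean Gaussian random effect with covariance proportional to the
standardized-genotype kinship matrix, Cholesky with a 1e-6 jitter),
observational noise (iid Gaussian), and covariates (a random linear
combination of standardized age ~ Uniform(20, 70) and sex ~
Bernoulli(0.5); only their variances matter after scaling). Causal SNPs
are drawn uniformly among sites with cohort MAF ≥ 0.05 and non-constant
ancestry-of-interest dosage (a constant dosage would make the ancestry
channel's budget unsatisfiable). All three genetic channels are co-located
at the causal set, consistent with the per-locus interaction term of the
LAAA model.

Budgets fix genetic effects at 60% of total variance: variant 12%, local
ancestry 6% (APA- and LAAA-kind), interaction 4% (LAAA-kind only), the
genetic remainder population structure; noise is 16% observational + 24%
covariates. The five-way grid adds two null allelic-only scenarios (CHB,
GIH ancestries) with no variant effect at all (structure takes the full
60%). Three phenotype kinds × sources × 3 causal-set replicates give 27
scenarios for the three-way and 45 for the five-way population.

**Exact scaling.** Because the three genetic channels share causal loci,
their raw components are correlated and naive per-component scaling would
only approximate the budget. Components are therefore sequentially
orthogonalized (order: variant, local, interaction, structure, covariates,
noise; each demeaned and residualized against the already-scaled ones),
standardized to unit empirical variance and multiplied by the square root
of their share. Y is the exact sum, has unit variance, and every realized
share equals its budget to numerical precision — which is what the
variance-budget checks assert at 1e-6. A non-orthogonalized mode is
available behind a flag for sensitivity analysis. A component that is
collinear with earlier ones while holding a positive budget raises an
error naming the component.

## Association testing

Sites with cohort minor-allele frequency strictly below 0.05 are removed
(a MAF of exactly 0.05 is kept). The major allele is defined per site on
the analysis cohort; an exact 50/50 tie goes to the alphabetically first
base. Dosages at a site are computed per haplotype as indicator
conjunctions — X_x counts major alleles, X^i counts ancestry-of-interest
labels, X^i_x counts major alleles on ancestry-of-interest haplotypes —
guaranteeing X^i_x ≤ min(X_x, X^i).

All five models are ordinary least squares with intercept, standardized
age, and sex; ancestry-aware models add global-ancestry proportion columns
with the smallest-mean component dropped (ties broken by declared source
order) to avoid collinearity with the intercept. The headline p-value is
the marginal t-test of the genetic term for single-term models and the
nested F-test of the genetic block for APA (2 df) and LAAA (3 df) — the
exact finite-sample test for a Gaussian linear model; marginal per-term
p-values are always reported too, so either hit definition (joint or
single-term) can be scored downstream, including the two-step
source-attribution style of analysis. Significance uses strict inequality
at 5×10⁻⁸.

The genome scanner projects the covariate block out of the phenotype and
the dosage columns once (QR-based Frisch–Waugh–Lovell) and solves the
small per-site normal equations batched over sites, with degrees of
freedom counted against the full design — algebraically identical to
fitting the full regression at every site, and verified against both
statsmodels (which backs the single-site `fit_site`) and an independent
normal-equations oracle to 1e-8. Sites whose genetic block is collinear
after projection (smallest eigenvalue ≤ 1e-10 of the block's trace) are
flagged, excluded from the significant set, and listed. Ancestry-aware
models run once per ancestry of interest; the pipeline scores the scan for
the phenotype's designated ancestry.

## Scoring

A true positive is a genome-wide-significant causal site; a false positive
is a significant non-causal site whose genotype r² with every causal site
is below 0.2 (the threshold is a standard clumping convention and
configurable; with LD-free source populations, admixture LD is the
dominant source of proxies). Counts are averaged over the three replicate
causal-set draws per scenario. Scenario labels follow the
"KIND-ANCESTRY" convention (e.g. `LAAA-LWK`).

## Reproducibility

A single master seed drives a run; every stage derives a child seed by
hashing the seed with a stage/scenario tag (SHA-256, reduced below 2³¹),
so adding scenarios never perturbs existing random streams and identical
configs reproduce byte-identical summaries.

## Problem sizes

Defaults are desk-scale: 500 admixed individuals and 10,000 sites per
preset, three replicates, chosen so a full two-model grid runs in well
under a minute per preset and the complete five-model × two-condition
study in tens of minutes. Calibration checks use pure-noise phenotypes on
a 150 × 10,000 cohort (20 seeds); the shared test cohorts are 120 × 2,500.
Full-study sizes (thousands of individuals, hundreds of thousands of
sites) are accepted via config.

## Limitations

* **No background LD**: sites are independent within source populations,
  so false-positive counts attributable to ancestral (pre-admixture) LD
  are conservative; only admixture LD is represented. A haplotype-copying
  extension flag is reserved.
* **Power at desk scale** is low in absolute terms (a 0.22 total causal
  variance over 10 SNPs in 500 individuals yields few hits at 5×10⁻⁸);
  the benchmark's object is the ordering of models, not absolute power.
* The corruption model emulates LAI error rates and their block structure,
  not reference-panel misspecification or the inference algorithm itself.
* Reference pools and ancestral contributors are treated as the same
  populations (no post-admixture drift between them).
* Continuous phenotypes only; no case-control models, linear mixed models,
  or multiple admixture waves for the five-way population.
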