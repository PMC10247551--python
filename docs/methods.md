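# Methods

`bonesnp` models the identification of highly degraded skeletal remains by
massively-parallel sequencing of a biallelic identity-SNP panel (90
autosomal + 34 Y-specific markers by default). This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish about real samples.

## Genotype calling

Calls follow the default rule set of commercial MPS genotyping software for
such panels. A locus is typed only when total coverage is ≥ 20 reads and
each strand carries more than 10 reads (strand totals are summed over both
alleles; the per-locus reading is the only one consistent with homozygote
calls near the 20× floor). With minor-allele read fraction m:

- m < 0.05 — clean homozygote of the major allele;
- 0.05 ≤ m ≤ 0.10 — homozygote with an imbalance alert (a low-level second
  allele, one of the contamination tells);
- m > 0.10 — heterozygote, MAF-flagged when m < 0.35.

The printed band edges of such software (10.1–35.0%, 65.0–89.1%, "5 to
10%") leave small gaps between adjacent percentages; we read them as
continuous cut-points at 0.05, 0.10 and 0.35 so every count vector gets
exactly one class. All edges are configurable in `CallThresholds`.
Hemizygous Y loci use the same gates; the majority allele is called and a
second allele above 10% is recorded as a Y drop-in annotation (a spurious
haplotype cannot be genuine in a single male source).

## Synthetic degraded samples

The generator reproduces the statistical regime of picogram bone extracts
rather than sequencing mechanics. Per locus and allele, surviving template
molecules are Poisson with mean

λ = (1 − f_c) · (T / 3.3 pg) · (n/2) · exp(−δ·L),

where T is template mass, n the genotype copy number, δ the per-bp
degradation rate and L the amplicon length. Defaults: T = 6.8 pg (the
median challenging-extract input; maximum regime 42 pg), δ = 0.005/bp —
together these give roughly half the loci dropping out on a 60–160 bp
panel, the observed failure rate of such extracts. Contamination is
molecular: a fraction f_c of template molecules comes from a second genotype
(laboratory carry-over, a single shared contaminant per cohort), not from
read-level artefacts. Each surviving molecule contributes
negative-binomially distributed reads (mean 100, per-molecule dispersion 2;
totals over c molecules use shape 2c). The per-molecule dispersion model is
deliberate: it yields balanced heterozygotes and full concordant profiles at
nanogram input while making single-molecule heterozygotes unbalanced enough
that about half of them earn a MAF flag — both regimes are observed in real
reference vs. challenging libraries. Sequencing error is a symmetric
per-read miscall (0.001) to the other panel allele; indel error is out of
scope for a biallelic SNP model. Reads are split across strands
binomially (0.5).

Cohorts mirror the study design: reference replicates at 1000 pg;
challenging libraries with log-normal inputs (median 6.8 pg, σ_log = 0.9);
a per-sample contaminant fraction that is 0 with probability 0.6 and
Uniform(0.05, 0.5) otherwise (the 40% contamination prevalence matches the
share of spurious-profile libraries such studies report; the mixture itself
is a modelling choice, not an inference). Every sample carries a truth
manifest (copies and read origins per allele), so fidelity metrics can be
verified against the generator exactly.

Synthetic frequencies draw the first-allele frequency Uniform(0.2, 0.8),
giving mean expected heterozygosity ≈ 0.44, close to the ≈ 0.46 of real
identity panels.

What the generator does *not* model: PCR-cycle dynamics and stutter-free
amplification artefacts, uracil-deamination damage, reference-bias in
alignment, and index hopping. Passing tests therefore establish correctness
of the statistical pipeline under a plausible low-template mechanism, not
calibration against any particular instrument.

## Reference, consensus, and fidelity accounting

Reference profiles require full, mutually concordant replicates; any
disagreement is an error naming the locus (never a majority vote).
Consensus profiles pool partial libraries Turchi-style: an allele enters
when called in ≥ `min_support` (default 2) libraries; two supported alleles
give a heterozygote (ties broken by supporting read depth, then
lexicographically); one gives a single-allele call exported as homozygous
but tagged, since support-1 loci cannot distinguish a homozygote from a
heterozygote with drop-out.

Against a reference, over autosomal loci called in both: ADO counts each
reference allele copy missing from the call (denominator: 2 × called loci —
uncalled loci are locus drop-out, a different phenomenon, so ADO stays in
[0, 1] and independent of typing rate); ADI counts one event per locus
carrying a non-reference allele, classified as hom→opposite-hom swap or
hom→het (a het reference cannot gain an allele at a biallelic locus).

## Semi-continuous likelihood ratios

For one locus with evidence set E and a known contributor carrying n_a
copies of allele a: each copy drops out independently with probability d
(homozygote loss d²), so a carried allele is seen with 1 − d^{n_a}; an
uncarried allele drops in with probability c·p_a (absence factor
1 − c·p_a). The locus likelihood is the product over the two panel alleles;
this is the standard presence/absence convention of semi-continuous
forensic software. Under the defence hypothesis one unknown contributor is
marginalised with Balding–Nichols θ-corrected genotype probabilities
*conditioned on the reference genotype* (sequential sampling formula
(m_aθ + (1−θ)p_a)/(1 + (n−1)θ)); without conditioning the θ correction
would be vacuous. θ defaults to 0.01. Frequencies are floored at 1/(2N+2),
N = 1000, before any likelihood use.

Three parameter conventions: LRd — defaults d = 0.1, c = 0.05; LRe — d
estimated by maximising the prosecution likelihood on a 0.01-step grid with
a floor of 0.1 (smallest maximiser on ties); LRa — the sample's actual
ADO/ADI frequencies, available only when the donor is known
(proof-of-concept accounting). The drop-out estimator includes reference
loci at which the evidence is uncalled (empty evidence = two drop-outs):
excluding them conditions on locus survival and systematically
underestimates d in degraded samples (the grid MLE would converge to
~0.3 when the truth is 0.6). Products are accumulated in log10; an exact
zero numerator (possible under actual parameters of zero) yields −inf,
reported as such.

Evidence loci that are uncalled carry no information and are excluded from
LR products; uncalled loci are *not* treated as evidence against either
hypothesis.

## Continuous likelihood ratios

The quantitative model treats read counts as the peak-height analogue:
reads for an allele with n contributor copies follow Gamma(shape =
(n/2)/ω², scale = μω²), so a full contributor yields μ expected reads per
locus with coefficient of variation ω. Reads below the analytical threshold
AT = 20 (matching the calling threshold) contribute the gamma mass below
AT (drop-out); an uncarried allele appears above AT only by drop-in, with
probability c·p_a and Exp(λ) excess reads (c = 0.05, λ = 0.05/read, both
fixed, as is common practice for pre-set drop-in parameters). Counts are
treated as continuous — above 20 reads discreteness is negligible. (μ, ω)
are fit per hypothesis by L-BFGS-B in log-space from a deterministic
multi-start (five-point decade ladder on μ around the mean called-locus
total, ω ∈ {0.2, 0.5, 1.0}); the unknown-contributor hypothesis
marginalises genotypes with the same θ-conditioned probabilities as the
semi-continuous model. Loci with all alleles below AT are excluded from the
fit, consistent with the evidence-profile convention above. No degradation
slope is fit: the panel's amplicons are uniformly short, and one fewer
parameter keeps the 3-locus minimum meaningful.

In the high-information limit (large μ, clean full-coverage matching
evidence, c = 0) the continuous LR reduces to the inverse θ-corrected match
probability, i.e. the semi-continuous LR at d = c = 0 — a useful
cross-model check, verified in the tests.

## Diagnostics and reporting

Verbal equivalents follow the ENFSI-style bands, read gap-free: LR within
[0.5, 2] — no support; (2, 1000) — weak/moderate; [1000, 10⁶] — strong;
above 10⁶ — extremely strong, with reciprocal values supporting the
opposite hypothesis. Heterozygosity excess (the biallelic-panel mixture
signal) uses the exact one-sided binomial tail against the expected
heterozygosity; HWE consistency of a single profile uses the exact
Poisson-binomial distribution of the heterozygote count (each locus its own
2pq Bernoulli; a genotype-count χ² is impossible with one genotype per
locus), with a minimum-likelihood two-sided tail. Group comparisons use a
pooled two-proportion z-test with a Fisher-exact fallback when any expected
cell is below 5. All report percentages are recomputed from raw counts.

## Problem sizes and reproducibility

Simulation-backed tests use 90-locus panels with 20–100 seeded replicates
per claim, and the acceptance script runs a 30-challenging-sample cohort,
100-replicate discrimination and drop-out-recovery experiments, a
20-replicate continuous-model recovery experiment, and a 30-sample
cross-model comparison. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; reruns of the pipeline with one
configuration are byte-identical, and every artifact records the seed and a
configuration hash.

## Known limitations

- Single-source hypotheses only: no mixture deconvolution, no kinship
  hypotheses, no Y-marker likelihood ratios (Y data feed diagnostics only).
- The drop-out grid MLE is a stand-in for proprietary estimators of
  commercial tools; only its floor (0.1) is anchored externally.
- LRa uses empirical ADO/ADI frequencies verbatim (clipped into [0, 0.99]);
  frequencies of exactly zero make a mismatching locus impossible and can
  legitimately drive the LR to 0 or the numerator to dominance.
- Continuous-model drop-in parameters are fixed, not fitted; strongly
  contaminated evidence is therefore penalised rather than explained.
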