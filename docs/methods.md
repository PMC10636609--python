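# Methods

## The measurement and the model

Metabolic labeling with 4-thiouridine (s⁴U) for a window of *t* hours
followed by recoding chemistry leaves T-to-C mismatches in sequencing
reads that derive from transcripts synthesized during the window. For a
gene *s* in condition *j*, the fraction of new transcripts is

θ[j,s] = 1 − exp(−k_deg[j,s] · t)

under first-order decay at steady state — fast-turnover transcripts
renew more of their pool during the label. The observed data are
per-read retained mutation counts *tc*, modeled as a two-component
Poisson mixture with rates parametrized on the log scale:

f(tc | θ, λₙ, λₒ) = I·θ · Pois(tc; e^λₙ) + (1 − I·θ) · Pois(tc; e^λₒ)

I ∈ {0,1} marks s⁴U-treated libraries; unlabeled controls (I = 0)
collapse to the background Poisson and anchor λₒ, which absorbs
reverse-transcription and sequencing errors. "PoissonLog" here always
means a Poisson whose rate is the exponential of the stated parameter.

Gene-level rates vary around global means through a non-centered
hierarchy:

- λ̄ₒ ~ Normal(−3, 1.5); λ̄ₙ[j] ~ Normal(−1, 1.5) per condition
- σₒ, σₙ[j] ~ HalfCauchy(0, 1.5) (Cauchy truncated to the positive axis)
- zₒ[s], zₙ[j,s] ~ Normal(0, 1.5)
- λₒ[s] = λ̄ₒ + σₒ·zₒ[s]; λₙ[j,s] = λ̄ₙ[j] + σₙ[j]·zₙ[j,s]
- θ[j,s] ~ Beta(1, 1), i.e. uniform — the flat choice, configurable.

The prior centers put the background near 0.05 mutations/read and the
new-RNA rate near 0.37/read, the scales where this chemistry operates.
The z-score prior scale of 1.5 (rather than the conventional 1.0) is
kept as specified and is configurable. λₒ[s] is shared across
conditions (background error is a property of the site/library
chemistry, not of the genotype); λₙ is per condition. By default
replicate libraries within a condition share one θ[j,s]; a
replicate-level θ option exists (`share_theta=False`).

Genes lacking at least one read in every sample are excluded before
fitting and reported; the mixture is poorly informed on genes with
missing libraries.

## Posterior computation

The sampler is an adaptive Metropolis-within-Gibbs scheme written for
this model's structure (no gradient-based backend is used). Per-read
counts are collapsed to tc histograms per (gene, condition, label
status) — sufficient statistics for the mixture — so sweep cost is
O(genes × conditions × max tc) regardless of read depth. One sweep:

1. Random-walk Metropolis on every λ-hierarchy parameter against the
   mixture-marginal likelihood (latent component assignments
   integrated out), with per-parameter step sizes adapted toward 0.44
   acceptance during warmup and frozen afterwards.
2. Interweaving moves on both hierarchies: a translation
   (λ̄ + d, z − d/σ) and a scale (σ·c, z/c) proposal, both
   likelihood-invariant, which decorrelate the global mean/scale from
   the gene-level offsets — in a non-centered parametrization with
   informative data these directions otherwise barely move.
3. A condition-level ridge move (λ̄ₙ + δ with every θ in the condition
   scaled by e^(−δ)) and per-gene ridge moves (λₙ + σε with
   θ·e^(−σε)): θ and λₙ are individually soft but their product —
   the labeled mean — is sharp, so axis-aligned updates crawl along
   this ridge while the joint proposal travels it.
4. Exact θ updates: latent assignments are imputed read-wise
   (binomially per histogram cell), then θ drawn from its conjugate
   Beta conditional. Steps 3–4 cycle three times per sweep.

Because the assignments are re-imputed after the marginal λ updates,
every step leaves the posterior over (θ, λ) invariant (a partially
collapsed Gibbs scheme; the marginal-then-impute ordering is what makes
it valid). Chains are seeded independently from one user seed;
identical settings reproduce identical draws. Convergence is summarized
by split-R̂ and bulk ESS (via ArviZ) with R̂ < 1.05 flagged as converged;
point estimates are posterior medians with equal-tailed credible
intervals throughout.

Two caveats established while validating the sampler: (i) the marginal
posterior of λ̄ₙ sits slightly below the profile-likelihood optimum
(a volume effect — integrating each gene's θ under a flat prior favors
lower rates, and the profile is flat to ~1 log-likelihood unit over
0.05); θ medians inherit a corresponding upward shift of ~0.02–0.03.
(ii) σ posteriors mix slowest when the true gene-level spread is near
zero (a boundary the half-Cauchy allows but random-walk proposals
explore sluggishly); neither affects θ point estimates materially.

## From fractions to rates and calls

Draw-wise transforms propagate posterior uncertainty exactly:
k_deg = −ln(1 − θ)/t per draw (θ = 1 clipped to 1 − 1e−9 with a
warning), k_syn = N·k_deg with N the upper-quartile-normalized mean
expression of the condition (counts per million of effective library
size; factors are 75th percentiles of positive counts over library
size, rescaled to geometric mean 1).

Fold changes between a reference and a perturbed condition:
L2FC_kdeg = log2(k_deg,b/k_deg,a) draw-paired; L2FC_N is a fixed
scalar from normalized counts with pseudocount 0.5 (a deliberate,
documented simplification — no negative-binomial differential
expression fit is performed); L2FC_ksyn = L2FC_N + L2FC_kdeg by
construction, so the steady-state identity holds on every draw. Then

frac_deg = ((|L2FC_kdeg| − |L2FC_ksyn|) / |L2FC_N| + 1) / 2,

bounded in [0, 1] by the reverse triangle inequality (the denominator
is taken in absolute value precisely so that the bound and the
directional reading hold; float residue is clipped). Genes with
|L2FC_N| ≤ 1e−6 are marked undefined. Classification: the 80%
equal-tailed interval of the frac_deg draws entirely above 0.5 →
stability-driven; below → synthesis-driven; else ambiguous. A
destabilized call additionally requires the 95% equal-tailed interval
of L2FC_kdeg to exceed zero (the interval masses are configurable; the
95% choice for calling is this package's decision — the upstream
protocol does not pin one).

## Mutation calling

An event is retained iff it is T>C in transcript orientation (a genomic
A>G on a minus-strand gene counts — the chemistry acts on transcript
uridines), base quality ≥ 40, at least 3 nt from both read ends
(offsets 0–2 excluded), and not at a masked site. Events failing a
filter are dropped individually; the read remains with its reduced tc,
and reads with tc = 0 are kept as observations. Proper unique pairs are
flag pairs {83,163} or {99,147}. SNP masking tests each site's control
mutation count against a background rate with a one-sided binomial
tail at α = 0.05; the background defaults to the pooled control
mutation fraction, re-estimated over unmasked sites until stable so
genuine SNPs do not inflate it. An external variant list (e.g. from a
dedicated variant caller) can be merged into the mask; variant calling
itself is out of scope. SAM/BAM input requires MD tags; mismatches are
reconstructed without the reference genome.

## The synthetic-data generator

`simulate_experiment` emulates the study design: two conditions ×
three replicates, each replicate one labeled and one unlabeled control
library; a 2 h label; per-gene k_deg log-normal around 0.2 h⁻¹
(half-life ≈ 3.5 h, mid-range for mammalian mRNA) with spread 0.5 on
the log scale; gene-level log-rate spread σₙ = σₒ = 0.15 around global
rates λ̄ₙ = −1, λ̄ₒ = −3 (the prior centers, the only stated scale
anchors); expected depth proportional to steady-state expression
k_syn/k_deg times a log-normal library factor (sd 0.1); optional SNP
sites (1% of sites, heterozygous: mutation probability 0.5, observed
in labeled and control libraries alike) recorded site-level for the
mask test. Reads are abstract records carrying tc directly — the
inference consumes nothing else — with an artifact decorator
(`read_records_with_artifacts`) that adds per-event qualities, offsets,
and filterable junk (low-quality, read-end, SNP-site events) for
exercising the calling rules end to end. Depth can be deterministic
("exact", the default, convenient for bookkeeping tests) or Poisson
("poisson", realistic shot noise).

What the generator does not emulate: alignment and mapping artifacts
beyond read-end events, PCR duplication, dropout or batch structure,
U-content variation between transcripts (every read sees the same
effective rate), and any departure from steady state during labeling.
Passing tests on synthetic data therefore demonstrate correctness of
the inference given the model's assumptions, not robustness to real
library pathologies.

## Validation studies and their design

The validation fixtures (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) are chosen to make the planted truth exact:

- **Recovery study** — 100 genes, two conditions, θ planted at
  {0.2, 0.5, 0.8} via k_deg, three 300-read labeled+control library
  pairs per condition, gene-level rate spread zero so the global rates
  are the per-gene truth. Measured: ≥ 90% of θ posterior medians within
  ±0.1 of truth; global log-rates within ±0.3 (typically ±0.1).
- **Planted-signal study** — 200 genes, 20 destabilized (k_deg × 2,
  k_syn unchanged, so expression halves), base k_deg log-normal around
  0.35 h⁻¹ (where a 2 h label is most informative), Poisson depth at
  300 reads/gene. Measured: ~half the planted genes are called at the
  95% interval with essentially zero false calls; a null simulation
  yields ≤ 1% calls.

The recall ceiling of the planted study is a read-depth limit, not an
implementation defect: with ~900 labeled reads (WT) and ~450 (KO,
halved by the expression drop), the θ posterior SD is 0.05–0.08 —
matching the Fisher information of the mixture — which puts the
posterior SD of L2FC_kdeg near 0.4 log2 units. The stability
classification (frac_deg's 80% interval clearing 0.5) then succeeds
for only ~55–65% of genuinely destabilized genes; recovering ≳90% of
two-fold stability changes would need several-fold deeper libraries.
The false-call side does not suffer: both gates must fail open
simultaneously for a null gene, which is rare at any depth.

## Numerical choices

Mixture terms are combined by log-sum-exp with the vanishing component
dropped at θ ∈ {0,1}; rate exponents are capped at e^30 inside the
sampler (any observable count is impossible there anyway). Equal-tailed
intervals use linear-interpolation quantiles. Upper-quartile factors
error on all-zero samples, naming the sample. frac_deg is computed
draw-wise (not from point estimates) with L2FC_N entering as a fixed
scalar, so its credible interval reflects kinetic uncertainty only.
Ties in gene-to-interval assignment during SAM parsing resolve to the
lexicographically first overlapping gene. The run manifest records the
config, input checksums, per-stage attrition counts and seeds;
identical inputs and seed reproduce every output byte except
timestamps.

## Known limitations

- L2FC_N from mean normalized counts with a pseudocount is noisier than
  a shrinkage differential-expression estimate; for short labels or
  shallow libraries the undefined/ambiguous band widens accordingly.
- The model assumes steady state over the labeling window; transcripts
  being actively induced or repressed violate θ = 1 − e^(−k·t).
- Reads are treated as independent; overlapping mate pairs can count a
  converted site twice.
- SNP detection from the per-read TSV flow is not possible (the table
  carries no genomic positions by design); it operates on SAM input or
  site-level control tables.
- The unlabeled-control background cannot separate sequencing error
  from low-level recoding leakage; λₒ absorbs both.
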