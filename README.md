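# tlkinetics

Bayesian kinetic analysis of nucleotide-recoding RNA-seq
(TimeLapse-seq / SLAM-seq style experiments).

In these experiments cells are fed 4-thiouridine (s⁴U) for a labeling
window of *t* hours; recoding chemistry converts incorporated s⁴U so
that reverse transcription reads it as C, marking reads from newly made
transcripts with T-to-C mutations. `tlkinetics` takes the analysis from
aligned reads to biology:

1. **Mutation calling** — count retained T-to-C events per read,
   dropping low-quality calls (phred < 40), events within 3 nt of a
   read end, and SNP/artifact sites detected from unlabeled control
   libraries (one-sided binomial test, p < 0.05) or supplied as a
   variant blacklist. Uniquely mapped proper pairs are selected by SAM
   flag pair (83/163 or 99/147).
2. **Kinetic inference** — a hierarchical Bayesian mixture model of the
   per-read mutation count *tc*:

   f(tc | θ, λₙ, λₒ) = I·θ · Pois(tc; e^λₙ) + (1 − I·θ) · Pois(tc; e^λₒ)

   where θ is the fraction of transcripts made during the labeling
   window, λₙ and λₒ are new-RNA and background log mutation rates, and
   I indicates s⁴U treatment (0 for control libraries). Gene-level
   rates vary around global means through a non-centered hierarchy
   (λₙ[j,s] = λ̄ₙ[j] + σₙ[j]·zₙ[j,s], weakly informative priors
   Normal(−1, 1.5) and Normal(−3, 1.5) on the global log-rates,
   HalfCauchy(0, 1.5) scales). Posteriors are sampled by an adaptive
   Metropolis-within-Gibbs scheme with conjugate θ updates.
3. **Rate decomposition** — fraction-new converts to a first-order
   degradation rate, k_deg = −ln(1 − θ)/t; with upper-quartile
   normalized expression N, synthesis is k_syn = N·k_deg, and on log2
   scale L2FC_N = L2FC_ksyn − L2FC_kdeg exactly. The statistic

   frac_deg = ((|L2FC_kdeg| − |L2FC_ksyn|) / |L2FC_N| + 1) / 2 ∈ [0, 1]

   attributes an expression change to stability (→1) versus synthesis
   (→0); a gene whose 80% credible interval of frac_deg clears 0.5 is
   classified stability- or synthesis-driven, and destabilized genes
   are called when additionally the 95% interval of L2FC_kdeg excludes
   zero.

A synthetic-data generator produces read tables, count matrices and
ground truth with exactly the statistical structure the model assumes,
so the whole pipeline is testable without sequencing data.

## Worked example

Simulate two genotypes (WT, KO; three replicate labeled+control library
pairs each, 2 h label), with six genes destabilized two-fold in KO, fit
the model and decompose:

```python
import tlkinetics as tk
from tlkinetics.simulate import planted_destabilization_config

cfg, planted = planted_destabilization_config(
    n_genes=60, n_destabilized=6, reads_per_gene=400, seed=17)
data = tk.simulate_experiment(cfg)

model = tk.PoissonMixtureKinetics(data.reads)
fit = model.fit(chains=2, warmup=500, draws=800, seed=1)

sample_conditions = dict(
    data.reads.drop_duplicates("sample_id")
        .set_index("sample_id")["condition"])
decomp = tk.StabilityDecomposition(
    fit, data.counts, sample_conditions, reference="WT", treatment="KO")
res = decomp.fit()
print(res.summary())
```

Output (planted genes were gene_0000, 0016, 0021, 0036, 0038, 0049):

```
Stability/synthesis decomposition
  reference: WT  treatment: KO
  genes analyzed: 60
  classes: ambiguous=51, stability_driven=6, synthesis_driven=3
  destabilized calls (95% CI): 5
  stabilized calls: 0
  top destabilized: gene_0021, gene_0036, gene_0049, gene_0000, gene_0016
```

Five of the six planted genes are called destabilized with zero false
calls: each shows expression down ~1 log2 unit (`l2fc_n ≈ −1`), a
degradation rate up ~1 log2 unit (`l2fc_kdeg_median ≈ 1.3`), and
`fracdeg_median = 1.0` — the expression loss is attributed entirely to
destabilization, as planted. `res.table` carries the full per-gene
output, `res.scatter_table()` the expression-change versus
degradation-contribution view, and `fit.summary()` the posterior
medians, 80% credible intervals and convergence diagnostics (R̂, ESS)
for every parameter.

The same pipeline runs from the shell:

```bash
tlkinetics simulate --n-genes 60 --reads-per-gene 400 --seed 17 --out sim/
tlkinetics run-all --reads sim/reads.tsv --counts sim/counts.tsv \
    --reference WT --treatment KO --seed 1 --out run/
tlkinetics report --results run/results.tsv --out run/
```

`tlkinetics call-mutations` produces the read table from SAM/BAM
alignments (MD tags required) and a BED gene annotation.

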