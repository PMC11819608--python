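# isodex

Joint Bayesian detection of differentially expressed transcript isoforms
from RNA-seq exon-region counts.

## The problem

Genes produce multiple isoforms that share exons, so exon-level read counts
mix the contributions of several transcripts, and two kinds of variability
confound naive comparisons: *within-sample* positional bias (read density
varies systematically along a transcript) and *between-sample*
overdispersion (abundance varies across biological replicates far beyond
Poisson noise).  `isodex` models both jointly and infers, per isoform, the
posterior probability that two phenotype groups differ in abundance —
rather than running a test on point estimates quantified separately.

It is aimed at researchers analyzing two-group bulk RNA-seq designs at
isoform resolution, and at methodologists who want a fully generative,
seedable simulator with ground truth to benchmark differential-transcript
callers.

## The model

Counts in exon region *i* (the disjoint segments of a gene's exonic union
split at all isoform boundaries) superpose latent per-isoform counts,
y[g,i,j] = Σ_t s[g,t,i]·y[g,t,i,j].  Each latent count is Poisson with mean

    γ[g,t,i,j] = x[g,i,j] · β[g,t,j] · exp(U[g,t,i]),
    U[g,t,i] ~ N(0, 1/τ[g,t])  with  Σ_i U[g,t,i] = 0,    τ ~ Gamma(a, b)

(the Poisson-Lognormal layer: x = L·N/10⁹ makes β FPKM-scale, U is the
positional bias), and abundances follow a Gamma-Gamma layer with a latent
differential state d per isoform:

    β ~ Gamma(α, λ),   λ ~ Gamma(α₀, ν),   ν ~ Gamma(a₀, b₀)

with one shared λ when d = 0 and independent group rates λ₁, λ₂ when d = 1.
A Metropolis-Hastings-within-Gibbs sampler (conjugate updates for β, τ, λ,
ν; constraint-preserving transfer proposals for U; an exact collapsed
Bernoulli update for d using the closed-form marginal with λ integrated
out; log-scale random walks for α, α₀) estimates P(d=1) and all
parameters.  Isoforms with P(d=1) > 0.75 are called differential.
See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import isodex as ix
from isodex.analysis import call_differential, evaluate_detection

dataset = ix.simulate_dataset(ix.SimulationConfig(n_genes=20, seed=7))
summary = ix.run_mcmc(dataset.gene_data(), dataset.design,
                      ix.MCMCConfig(n_iter=1500, burn_in=750, seed=8))
print(summary.to_table().head(3))
ev = evaluate_detection(call_differential(summary, threshold=0.75),
                        dataset.truth_table())
print(ev.precision, ev.recall, ev.f_score)
```

prints (about a minute on one CPU):

```
 gene_id transcript_id  prob_differential  mean_group1  mean_group2  snr_db
gene0000   gene0000.t1              0.997        3.594        9.385   0.678
gene0000   gene0000.t2              0.719        2.568        4.808  -1.160
gene0000   gene0000.t3              0.141        3.356        3.818 -15.088

at P(d=1) > 0.75: precision 0.909, recall 0.769, F 0.833
```

`prob_differential` is the posterior probability that the two groups draw
this isoform's abundance from different Gamma rates; `mean_group1/2` are
posterior-mean FPKM-scale abundances; `snr_db` is the estimated effect
size 10·log10((μ₁−μ₂)²/(σ₁²+σ₂²)).  The first isoform (true effect
0.7 dB) is confidently detected; the third (−15 dB, i.e. noise-dominated)
is not.  The `examples/` directory holds this and three more narrative
scripts (gene-model construction, exact SAM round-trip, permutation
enrichment).

A thin CLI wraps the same functions:

```bash
isodex simulate --seed 3 --out data/ --sam
isodex count --models data/gene_models.tsv --out counted/ data/sam/*.sam
isodex run --data data/ --out results.tsv --iterations 4000 --burnin 2000
isodex evaluate --results results.tsv --truth data/truth.tsv --out eval.json
isodex enrich --expr fc.tsv --gene-set set.txt --out enrich.tsv
```

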