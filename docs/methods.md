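# Methods

## The model

`isodex` detects differentially expressed transcript isoforms from RNA-seq
read counts aggregated over *exon regions* — the disjoint segments obtained
by cutting a gene's exonic union at every isoform's exon boundaries.  Because
isoforms share exons, the observed count in region *i* of gene *g* in sample
*j* superposes latent per-isoform counts:

    y[g,i,j] = Σ_t  s[g,t,i] · y[g,t,i,j]

with `s` the binary isoform-by-region inclusion matrix.  Two layers describe
the two kinds of variability seen in real data.

**Within-sample layer (Poisson-Lognormal).**  The latent count of isoform
*t* at region *i* is Poisson with mean

    γ[g,t,i,j] = x[g,i,j] · β[g,t,j] · exp(U[g,t,i]),

where `x = L_i · N_j / 1e9` is region length weighted by library size (so β
is FPKM-scale), and `U` is a positional log-dispersion capturing sequencing
bias along the transcript (3'/5' trends, middle-peaked coverage).  `U` has a
Normal(0, 1/τ) prior constrained to sum to zero over the regions the isoform
includes — the constraint separates positional shape from overall abundance
— and τ ~ Gamma(a, b) sets how strong the positional bias may be.

**Between-sample layer (Gamma-Gamma with latent differential states).**
Abundances across samples follow β ~ Gamma(α, λ).  A binary state d per
isoform says whether the two phenotype groups share one rate λ (d = 0) or
draw separate rates λ₁, λ₂ (d = 1), each rate having a Gamma(α₀, ν) prior
and ν ~ Gamma(a₀, b₀).  The posterior probability P(d = 1 | data) is the
quantity of interest; an isoform is called differential when it exceeds
0.75 (strict inequality).

All Gamma distributions use the shape–rate parameterization
(mean = shape/rate); the additive rate update of the τ conditional forces
this choice.

## Inference

A Metropolis-Hastings-within-Gibbs sampler updates, per gene and iteration:

1. **Latent counts** — each observed region count is split among the
   covering isoforms by a multinomial with probabilities ∝ γ (Poisson
   superposition).  This augmentation makes the β update conjugate; the
   split is exact by construction (counts always re-sum to y).
2. **β** — Gamma(α + latent reads, λ_group + Σ x·e^U) conjugate draw.
3. **U** — pairwise-transfer Metropolis: each included region is paired
   with a random other included region and a transfer (U_i+δ, U_i′−δ),
   δ ~ N(0, σ_U²), is proposed, preserving the sum-to-zero constraint to
   machine precision by construction.  One proposal per included region per
   sweep touches every coordinate while keeping cost linear in region count.
   The acceptance ratio uses the Poisson likelihood of the two affected
   region totals plus the Normal prior terms.
4. **τ** — conjugate Gamma(a + n_regions/2, b + ΣU²/2).
5. **d** — exact collapsed Bernoulli conditional.  Because the Gamma-Gamma
   marginal of a group's abundances with λ integrated out has the closed
   form

       m(β₁..β_J′) = ν^α₀ Γ(α₀+J′α) / (Γ(α₀) Γ(α)^J′)
                     · (Πβ)^{α−1} / (ν+Σβ)^{α₀+J′α},

   P(d=1 | β) = π₁ m(β₁)m(β₂) / [π₁ m(β₁)m(β₂) + (1−π₁) m(β_all)] can be
   computed exactly in log space — a valid Gibbs kernel for the same
   posterior that avoids trans-dimensional moves over (d, λ₁, λ₂).  The
   rates λ are then regenerated conjugately under the new d.
6. **Global α, α₀** — log-scale Metropolis random walks (Jacobian included)
   with diffuse Gamma(0.01, 0.01) priors; **ν** — conjugate Gamma.

Initialization is deterministic and data-informed: U = 0, τ = α = α₀ = ν =
λ = 1, d = 0, β from method-of-moments (Σ s·y)/(Σ s·x) floored at 1e−3.
A single seeded PCG64 generator consumed in the fixed update order makes
runs bit-reproducible.  Genes with zero counts in every sample are flagged
`not_estimable` and report the prior π₁.

### Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| N / burn-in | 4000 / 2000 | chain length; halved totals are adequate at ≤100-gene scale |
| σ_U | 0.2 | U-transfer proposal SD (log scale); acceptance typically 0.2–0.4 |
| σ_logα, σ_logα₀ | 0.3 | shape random-walk scales |
| a, b | 1, 1 | τ prior — weakly informative around τ ≈ 1 |
| a₀, b₀ | 1, 1 | ν prior |
| π₁ | 0.5 | prior P(d = 1); indifferent by default |
| threshold | 0.75 | posterior probability cut for calling (strict >) |
| abundance filter | 10 % | median relative abundance cut (strict >) |

The global α acceptance rate falls below 0.1 on large datasets (the
conditional tightens as isoform-samples accumulate); this only slows mixing
of α, which is nuisance-level for detection, and is logged rather than
asserted.

## Signal-to-noise convention

Effect sizes are summarized as SNR_dB = 10·log10((μ₁−μ₂)²/(σ₁²+σ₂²)) on
abundances, the standard signal-power over noise-power ratio; "moderately
differential" denotes the −3 to −1 dB band.  Equal means report −∞ as a
sentinel; zero variance in both groups is rejected as degenerate.

## The simulator

Datasets are drawn forward from the model itself.  Defaults are the
standard recovery conditions: 100 genes, 2–3 isoforms each (isoform 1
spans all 4–8 regions, so shared exons and full region coverage are
guaranteed; others keep the first region plus a random subset), region
lengths 200–1000 bp with 100–500 bp introns, J₁ = J₂ = 10 samples at 2·10⁷
mapped reads, half the isoforms differential with abundance SNR in the
0–5 dB band, and an even flat/middle-peaked bias mix with amplitude 0.5.
True α = 4, α₀ = 2, ν = 1 give FPKM-scale abundances around 2 and
region counts in the tens — typical of a moderately expressed gene.

Differential effects are injected by scaling one group's rate λ by the
ratio that yields a requested expected SNR (expected SNR is
α(1−r)²/(1+r²) for rate ratio r, so α = 4 caps the expected effect at
6 dB), then rejecting until the *realized* SNR of the drawn abundances
lands in the target band (≤100 redraws; misses keep the nearest draw and
are flagged, never silently accepted).

Emitted reads are single-end, non-junction-spanning (length 75, clipped to
the region, placed uniformly), so midpoint counting reproduces the count
tensor exactly.  The simulator does **not** emulate sequence-level realism —
base qualities, GC/hexamer effects, junction reads, paired ends, mapping
ambiguity — so passing recovery tests demonstrates correctness of the
estimator under the model, not robustness to alignment artifacts in real
libraries.

## Counting rules

A read is assigned by the midpoint of its aligned reference span
(CIGAR-aware) to the unique region containing that base; boundary-spanning
reads are therefore never double-counted, and reads hitting no region are
reported as unassigned.  Secondary and unmapped records are skipped;
counting is unstranded.  These are documented package choices — boundary
handling has no single field convention.

## Evaluation and downstream analysis

Calls use strict thresholds (P > 0.75; median relative abundance > 10 %).
A gene is differential iff ≥ 1 isoform is.  Detection is scored by
precision/recall/F against simulation truth, optionally split at −3/−1 dB.
The permutation enrichment statistic for a transcript set on a time-course
fold-change matrix uses the mean log2 fold change per time point, a null of
100,000 same-size row subsets drawn without replacement, the add-one
p-value convention p = (1+k)/(K+1) (never exactly zero), and score
−log10 p; the test is one-sided (≥) by default with a two-sided flag, since
enrichment direction conventions vary.  A Welch t-test + Benjamini-Hochberg
baseline caller on estimated FPKM is included solely as a comparison arm
for power experiments.

## Numerical notes

- All densities are computed in log space; the collapsed marginal is finite
  for counts up to 10⁶ and abundances up to 10⁵.
- Zero Poisson rate with a positive count yields −∞ log-density (a valid
  value), not an exception.
- The U transfer keeps Σ U conserved to ~10⁻¹⁴ per sweep; drift over a full
  chain stays far below the 10⁻¹⁰ assertion bound.
- Problem sizes in the validation suite (50–100 genes, chains of 300–4000
  iterations, 60-gene power studies) were chosen as the smallest sizes at
  which the statistical contracts are sharp; all are single-CPU runs.

## Known limitations

- Junction-spanning and multimapped reads are out of scope for counting;
  real-data use should pre-filter to primary alignments.
- The collapsed d-kernel targets the exact posterior but its chain dynamics
  need not match a sampler that proposes (d, λ) jointly.
- Single-sample groups cannot support the SNR summary (undefined sample
  variance); such isoforms are flagged.
- No adaptive proposal tuning or multi-chain convergence automation; traces
  are exposed for external diagnostics.
- No mid-run checkpoint/resume: chains at the supported scale finish in
  minutes and are bit-reproducible from their seed, so a crashed run is
  rerun rather than resumed.
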