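# Methods

## Scientific setting

`operonmeta` pools two-condition (treatment vs. control) microarray studies
of one biological system and reports, for every gene, the posterior
probability `D_g` that it is differentially expressed.  Two platform types
are modelled.  Spotted two-color arrays contribute one normalized
log-expression ratio per gene per slide, with replicate slides nested in
repeated experiments.  In-situ synthesized oligonucleotide (ISO) arrays
additionally measure each gene with up to four probes per slide, adding a
probe level beneath the slide level.  Every slide is standardized to zero
mean and unit sample SD (n−1 denominator) before modelling, so all model
scales below refer to the standardized scale.

In prokaryotes, genes inside one operon are co-transcribed and their
log-expression *ratios* between two steady-state conditions are expected to
be similar.  The package therefore offers two models:

* **Independence model** — every gene's mean effect is independent of all
  other genes.
* **Operon model** — genes are partitioned into units: operons (two or more
  genes) and singletons.  The differential-expression indicator and the
  spike-and-slab mixture act at the unit level, and a gene's mean is a
  precision-weighted compromise between its own data and the operon mean.
  Singleton units behave exactly as in the independence model.

## Model

Per study `j` (studies are modelled separately; per-study means are never
pooled into one overall effect):

```
spotted:  y[j,g,e,s]   ~ N(mu[j,g,e],     sigma2_slide[j])
oligo:    y[j,g,b,e,s] ~ N(omega[j,g,e,s], sigma2_probe[j])
          omega[j,g,e,s] ~ N(mu[j,g,e],   sigma2_slide[j])
both:     mu[j,g,e]    ~ N(theta[j,g],    sigma2_exp[j])
```

Independence model: `theta[j,g] ~ N(0, tau0_sq)` if `I_g = 0`, else
`N(0, tau1_sq)`, with `I_g ~ Bernoulli(p)` and `p ~ Beta(a, b)`.

Operon model: for a gene in operon unit `n`,
`theta[j,g] ~ N(xi[j,n], sigma2_op[j])` with the mixture on the unit mean
`xi[j,n] ~ N(0, tau_{I_n}^2)`, `I_n ~ Bernoulli(p)`.  One operon variance
`sigma2_op[j]` is shared by all operons within a study.  `D_g` for an
operon member is the posterior probability of its unit's indicator, so `D`
is constant within an operon by construction.

Slide and experiment variances are shared across genes within a study and
carry conjugate scaled inverse chi-squared priors; the probe variance is a
plug-in constant.  Sharing variance components across genes keeps every
full conditional conjugate and matches the common-probe-variance and
common-operon-variance structure of the rest of the hierarchy.

## Prior elicitation

All variance scales are pooled from the data across genes:

* slide scale `s2_s`: mean over (gene, experiment) of the sample variance
  of slide-level gene values within the experiment (oligo slide values are
  probe means);
* experiment scale `s2_e`: mean over genes of the sample variance of
  per-experiment gene means (this estimator targets
  `sigma2_exp + sigma2_slide/S` and is therefore mildly conservative);
* probe variance: pooled sample variance of probes around their
  (gene, experiment, slide) mean, `sum SS / sum (B−1)`;
* operon scale `s2_o`: mean over multi-gene operons of the within-operon
  sample variance of overall gene means.

Degrees of freedom default to ν = 3 for every scaled inverse chi-squared
prior — weakly informative while keeping a finite prior mean.  The mixture
defaults are `tau0_sq = 0.01` (spike; SD 0.1 on the standardized scale,
i.e. practically non-expressed) and `tau1_sq = 4` (slab; SD 2,
accommodating strong effects), with a flat Beta(1, 1) prior on `p`.  All
are user-overridable.

## MCMC

Posteriors come from a systematic-scan Gibbs sampler; every full
conditional is conjugate (normal-normal for all means, scaled inverse
chi-squared for variances, Beta for `p`).  The scan per iteration is:
probe means → experiment means → indicators and `p` → unit/gene means →
variances.

**Blocked indicator update.**  Indicators and the means they govern are
drawn as one block.  `I` is sampled with the unit means integrated out of
its conditional: for the independence model the mixture densities are
evaluated at the per-study data-level mean `theta_hat[j,g]`
(= mean of `mu[j,g,·]`) with its sampling variance `sigma2_exp/E` added to
`tau^2`; for an operon unit the member-averaged data mean is used with
variance `(sigma2_op + sigma2_exp/E)/K` added.  The unit means (`xi`, then
`theta`) are then redrawn given the new indicator, which completes a valid
joint draw from the (I, xi, theta) block.  The alternative — conditioning
the indicator on the current `theta` — is also a valid Gibbs step but mixes
pathologically under a tight spike: a truly expressed gene whose mean has
been shrunk toward zero under `I = 0` essentially never escapes the spike
(escape probabilities of order 10⁻³), which biases `p` and `D` severely at
any practical chain length.  The blocked form is therefore the only update
the sampler uses.

Defaults: 6,000 iterations, 1,000 burn-in, thinning 5 (1,000 retained
draws).  One integer seed drives a single `numpy` PCG64 generator for the
whole chain; identical data + config + seed reproduce results bit for bit.
Non-finite parameters abort the chain with the iteration number.  On a
single CPU a default-length chain on the canonical 3,000-gene two-study
data takes roughly 10 s.

## Decision statistics

* Calls: gene `g` is called at threshold γ when `D_g ≥ γ` (closed
  inequality).
* IDR: fraction of meta-analysis calls made by no individual study at the
  same γ; tIDR restricts numerator and denominator to genes simulated as
  truly differentially expressed.
* peFDR of a call set: mean of `1 − D_g` over called genes (hence bounded
  by `1 − γ`).  `genes_at_pefdr` ranks genes by `D` (stable ties by input
  order) and returns the largest prefix whose running peFDR stays at or
  below the target.
* The single-study baselines for IDR/tIDR are independence-hierarchy fits
  of each study alone (`J = 1`), shared by both meta-analysis models — one
  separate analysis per study, mirroring the single per-study curves of the
  comparison figures.  Using operon-model single-study fits instead would
  let the baseline borrow strength within operons and would invert the
  expected meta-vs-single ordering.

## Synthetic-data generator

The generator mirrors the operon model's generative assumptions:

1. operon structure: sizes drawn from a geometric distribution truncated to
   {2..6} until ~55% of genes lie in operons (Geobacter-like); remaining
   genes are singletons;
2. unit-level DE assignment with probability `p_s` (whole operons DE or
   not), so operon members share DE status by construction;
3. per study, DE units draw a unit mean from `N(0, effect_sd²)` and null
   units from `N(0, null_sd²)`; operon members scatter around the unit
   mean with SD `operon_sd`; singletons take the unit mean exactly;
4. studies layer experiment, slide and (oligo) probe noise and standardize
   each slide.

Defaults: `effect_sd = 2.0` and `null_sd = 0.1` — the square roots of the
analysis defaults `tau1_sq = 4` and `tau0_sq = 0.01`, so that the
generator's unit-mean mixture matches the model's spike and slab and the
calibration properties (posterior of `p`, peFDR vs. realised FDR) are
checked under a well-specified generator; `operon_sd = 0.2`,
`exp_sd = 0.5`, `slide_sd = 0.5`, `probe_sd = 0.6` on the
pre-standardization scale.  Canonical designs: spotted = 3 experiments × 2
slides; oligo = 2 experiments × 2 slides × 4 probes.  The two-study
scenario pairs one spotted with one oligo study; the five-study scenario
adds one spotted and two oligo studies whose noise SDs are jittered ±30%
(one inflated spotted, one deflated and one inflated oligo), i.e.
"somewhat outside" the base range.  All randomness flows from the scenario
seed.

What the generator does **not** emulate: real-data features such as
intensity-dependent dye bias, missing spots, gene-specific variances,
correlated probes within a gene, or operons whose structure breaks down
under a condition.  Passing the simulation-based checks therefore
demonstrates correctness of the inference machinery and the qualitative
benefit of borrowing strength, not robustness to those violations.

Slide standardization is a deliberate residual misspecification: it
rescales each slide by its empirical SD (≈ 0.85–1.05 under the defaults),
so the effective spike/slab variances seen by the model differ from
`tau0_sq`/`tau1_sq` by up to ~40%.  This matches how the method is applied
to real data, where the analysis scale is always the standardized one.

## Problem sizes used in the checks

The packaged checks run the canonical 3,000-gene scenarios with
default-length chains for the comparison-table quantities, 10 replicates
(default chains) for peFDR-vs-true-FDR calibration, 20 replicates at
2,000-iteration chains for the coverage check of `p`, and micro-instances
(2–3 genes) for brute-force posterior validation, keeping the full suite in
the minutes range on one CPU.

## Known limitations and open choices

* Slide/experiment variances shared across genes within a study (see
  above); gene-specific variants would break conjugacy of the simple scan.
* The spike/slab variances are fixed constants, not estimated; grossly
  mis-scaled data (not slide-standardized) will mis-calibrate `D`.
* The operon map is taken as given and identical across studies; partial
  or condition-dependent operon membership is out of scope.
* Coverage of the nominal value `p_s` by the 90% posterior interval of `p`
  is intrinsically borderline at 3,000 genes: the posterior (correctly)
  concentrates on the replicate's *realised* DE fraction, whose binomial
  fluctuation around `p_s` is comparable to the interval half-width, so the
  frequentist coverage of the fixed `p_s` hovers at ≈ 83–88% (measured
  over 60 replicates) rather than safely above 90%.  Slide
  standardization's rescaling of the effective spike/slab variances
  contributes a small additional bias.
* Missing cells are masked and excluded from all sums; the models assume
  missingness is non-informative.
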