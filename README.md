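# operonmeta

Bayesian meta-analysis of multi-platform microarray studies with
operon-aware borrowing of strength.

## The problem

Independent two-condition expression studies of the same biological system
— say a spotted two-color array study and an in-situ synthesized
oligonucleotide (ISO) array study of the same pathway — are routinely
analysed in isolation, wasting the extra replication that pooling would
buy.  Existing Bayesian meta-analysis models also assume every gene's mean
effect is independent of all other genes.  In prokaryotes that assumption
discards real structure: genes in one operon are co-transcribed, and their
log-expression ratios between two steady-state conditions are expected to
be similar.

`operonmeta` implements two hierarchical mixture models for pooling
studies, fitted by Gibbs sampling:

* **Independence model** — per study *j*, gene *g*:
  `y_jgse ~ N(mu_jge, sigma2_slide_j)` (spotted; an extra probe level
  `y_jgbse ~ N(omega_jgse, sigma2_probe_j)` for ISO arrays),
  `mu_jge ~ N(theta_jg, sigma2_exp_j)`, and a spike-and-slab prior
  `theta_jg ~ N(0, tau0^2)` when `I_g = 0` vs `N(0, tau1^2)` when
  `I_g = 1`, `I_g ~ Bernoulli(p)`.
* **Operon model** — genes are partitioned into units (operons of ≥ 2
  genes plus singletons); operon members satisfy
  `theta_jg ~ N(xi_jn, sigma2_op_j)` and the spike-and-slab mixture with
  indicator `I_n` acts on the operon mean `xi_jn`.  A weak-effect gene can
  be rescued by the pooled evidence of its operon neighbours.

The inferential output is `D_g = Prob(I = 1 | data)`, the posterior
probability that gene *g* (or its operon) is differentially expressed.
Decision statistics built on `D`: threshold calls (`D_g ≥ γ`), the
integration-driven discovery rate (IDR) and its truth-restricted variant
tIDR, the posterior expected FDR (mean of `1 − D` over called genes), and
true discoveries among the top-k genes.  A seeded generator simulates the
canonical evaluation scenarios (3,000 genes, 5/10/25% DE, Geobacter-like
operon structure, two-study and five-study designs).

See `docs/methods.md` for the full model, priors, sampler and generator
details.

## Worked example

Simulate the canonical two-study scenario (one spotted + one ISO study,
3,000 genes, 5% differentially expressed), fit both models jointly and
each study separately, and evaluate:

```bash
operonmeta reproduce --scenario two_study --ps 0.05 --n-genes 3000 \
    --seed 1 --out-dir report/
```

which prints (about two minutes on one CPU):

```
       model  tIDR_gamma_0.95  true_genes_peFDR_0.05  true_genes_top_150  posterior_mean_p
independence         0.060606                    110                 116          0.053065
      operon         0.148148                    118                 124          0.051132
```

Reading: at call threshold γ = 0.95, 14.8% of the operon model's true
discoveries were missed by both single-study analyses (6.1% for the
independence model) — the information gained by pooling.  Controlling the
posterior expected FDR at 5%, the operon model recovers 118 of the 146
truly DE genes vs 110 for the independence model, and it also places more
true genes in the top 150 (5% of 3,000).  The posterior mean of `p` is
close to the simulated 5%.  `report/` contains the posterior tables,
tIDR-vs-γ and true-genes-vs-peFDR curves (TSV + PNG), all stamped with the
config hash and seed.

The same subcommands work on user-supplied long-format TSV tables
(`gene experiment slide [probe] value`) and a two-column gene→operon map;
see `operonmeta --help` (subcommands: ingest, priors, simulate, fit,
evaluate, reproduce).

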