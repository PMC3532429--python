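"""Gibbs sampler for the gene-independence meta-analysis model.

Hierarchy, per study j (studies are modelled separately; per-study mean
effects are never pooled into one overall effect):

* spotted arrays:  y[j,g,e,s]   ~ N(mu[j,g,e],    sigma2_slide[j])
* oligo arrays:    y[j,g,b,e,s] ~ N(omega[j,g,e,s], sigma2_probe[j])
                   omega[j,g,e,s] ~ N(mu[j,g,e],  sigma2_slide[j])
* both:            mu[j,g,e]    ~ N(theta[j,g],   sigma2_exp[j])
                   theta[j,g]   ~ N(0, tau0_sq)  if I[g] = 0
                   theta[j,g]   ~ N(0, tau1_sq)  if I[g] = 1
                   I[g] ~ Bernoulli(p),  p ~ Beta(a, b)

``sigma2_slide`` and ``sigma2_exp`` carry scaled inverse chi-squared priors
and are shared across genes within a study; ``sigma2_probe`` is a plug-in
constant.  The sampler is a systematic-scan Gibbs chain (probe means ->
experiment means -> indicators and p -> gene means -> variances); every
full conditional is conjugate.  Indicators and gene means are updated as
one block: I[g] is drawn with theta integrated out of its conditional (the
mixture densities are evaluated at the per-study data means with their
sampling variance added to tau^2), after which theta is redrawn given the
new I[g].  Conditioning I on the current theta instead is valid but mixes
pathologically under a tight spike, because a truly expressed gene whose
theta has been shrunk to the spike almost never escapes it.  The
inferential output is D[g], the posterior probability that gene g is
differentially expressed, estimated as the mean of I[g] over retained
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import OLIGO, SPOTTED, MetaDataset
from .priors import PriorSpec

__all__ = [
    "McmcConfig",
    "ChainState",
    "PosteriorResult",
    "normal_posterior",
    "sample_probe_means",
    "sample_experiment_means",
    "sample_gene_means",
    "sample_variance",
    "indicator_probability",
    "sample_indicators",
    "sample_p",
    "init_state",
    "run_chain",
]


@dataclass
class McmcConfig:
    """Chain settings: total iterations, discarded burn-in, thinning
    interval between retained draws, and the master seed."""

    iterations: int = 6000
    burn_in: int = 1000
    thinning: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= self.burn_in:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class ChainState:
    """One MCMC state.  Per-study lists hold arrays whose shapes depend on
    each study's design; ``indicator`` is per gene for the independence
    model and per unit for the operon model."""

    omega: list[np.ndarray | None]      # oligo within-slide gene means (G,E,S)
    mu: list[np.ndarray]                # experiment-level gene means (G,E)
    theta: np.ndarray                   # study-level gene means (J,G)
    xi: np.ndarray | None               # unit means (J,U); None for model 1
    sigma2_slide: np.ndarray            # (J,)
    sigma2_exp: np.ndarray              # (J,)
    sigma2_op: np.ndarray | None        # (J,); None for model 1
    indicator: np.ndarray               # (G,) or (U,) in {0,1}
    p: float
    rng: np.random.Generator = field(repr=False)


@dataclass
class PosteriorResult:
    """Post burn-in summaries of one chain."""

    genes: list[str]
    D: np.ndarray                       # (G,) posterior prob of DE per gene
    theta_mean: np.ndarray              # (J,G)
    p_draws: np.ndarray
    model: str
    iterations: int
    burn_in: int
    thinning: int
    seed: int
    unit_of_gene: np.ndarray | None = None
    unit_size: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return len(self.p_draws)


# ---------------------------------------------------------------------------
# conjugate full-conditional kernels
# ---------------------------------------------------------------------------

def normal_posterior(data_sum, n, data_var, prior_mean, prior_var):
    """Posterior (mean, var) of a normal mean given ``n`` observations with
    known variance ``data_var`` summing to ``data_sum`` and a
    N(prior_mean, prior_var) prior: precision n/data_var + 1/prior_var."""
    precision = n / data_var + 1.0 / prior_var
    mean = (data_sum / data_var + prior_mean / prior_var) / precision
    return mean, 1.0 / precision


def sample_probe_means(rng, probe_sum, probe_count, sigma2_probe, mu, sigma2_slide):
    """Draw omega[g,e,s] given its observed probes and the slide prior
    N(mu[g,e], sigma2_slide); cells with no observed probe fall back to the
    prior."""
    mean, var = normal_posterior(
        probe_sum, probe_count, sigma2_probe, mu[..., None], sigma2_slide
    )
    return mean + np.sqrt(var) * rng.standard_normal(mean.shape)


def sample_experiment_means(rng, slide_sum, slide_count, sigma2_slide, theta, sigma2_exp):
    """Draw mu[g,e] given its slide-level values (observed y for spotted,
    omega for oligo) and the experiment prior N(theta[g], sigma2_exp)."""
    mean, var = normal_posterior(
        slide_sum, slide_count, sigma2_slide, theta[:, None], sigma2_exp
    )
    return mean + np.sqrt(var) * rng.standard_normal(mean.shape)


def sample_gene_means(rng, mu_sum, n_exp, sigma2_exp, prior_mean, prior_var):
    """Draw theta[g] given its experiment means and a N(prior_mean,
    prior_var) prior; the prior is the spike/slab component in model 1 and
    the operon mean in model 2."""
    mean, var = normal_posterior(mu_sum, n_exp, sigma2_exp, prior_mean, prior_var)
    return mean + np.sqrt(var) * rng.standard_normal(np.shape(mean))


def sample_variance(rng, df0, scale0, ss, m):
    """Draw from the scaled inverse chi-squared full conditional with prior
    (df0, scale0), residual sum of squares ``ss`` over ``m`` terms:
    df = df0 + m, scale = (df0*scale0 + ss)/df."""
    df = df0 + m
    return (df0 * scale0 + ss) / rng.chisquare(df)


def indicator_probability(values, p, tau0_sq, tau1_sq, inflation=0.0):
    """Posterior Prob(I = 1) for each unit given its per-study means.

    ``values`` has shape (J, U); the probability is
    p * prod_j N(v_j; 0, tau1_sq + c_j) over the two-component mixture
    total, evaluated in log space for stability.  ``inflation`` (scalar or
    broadcastable to ``values``) is the sampling variance c_j of each entry
    around the latent unit mean: zero when conditioning on the unit means
    themselves, positive in the blocked update that integrates them out.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    c = np.broadcast_to(np.asarray(inflation, dtype=float), values.shape)
    v1 = tau1_sq + c
    v0 = tau0_sq + c
    log1 = (-0.5 * np.log(2 * np.pi * v1) - 0.5 * values**2 / v1).sum(axis=0)
    log0 = (-0.5 * np.log(2 * np.pi * v0) - 0.5 * values**2 / v0).sum(axis=0)
    log_odds = np.log(p) - np.log1p(-p) + log1 - log0
    return 1.0 / (1.0 + np.exp(-log_odds))


def sample_indicators(rng, values, p, tau0_sq, tau1_sq, inflation=0.0):
    prob = indicator_probability(values, p, tau0_sq, tau1_sq, inflation)
    return (rng.random(prob.shape) < prob).astype(np.int8)


def sample_p(rng, a, b, k, n_units):
    """Conjugate Beta(a + k, b + U - k) draw for the DE proportion."""
    return float(rng.beta(a + k, b + n_units - k))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _StudyCache:
    """Per-study sufficient statistics that never change during sampling."""

    def __init__(self, study, study_priors):
        self.platform = study.platform
        self.G, self.E, self.S = study.n_genes, study.n_experiments, study.n_slides
        if study.platform == SPOTTED:
            self.slide_sum = (study.values * study.mask).sum(axis=2)  # (G,E)
            self.slide_count = study.mask.sum(axis=2)                 # (G,E)
            self.y = study.values
            self.mask = study.mask
            self.n_obs = int(study.mask.sum())
        else:
            self.probe_sum = (study.values * study.mask).sum(axis=3)  # (G,E,S)
            self.probe_count = study.mask.sum(axis=3)                 # (G,E,S)
            self.probe_var = study_priors.probe_var
            if self.probe_var is None:
                raise ValueError("oligo study requires a plug-in probe variance")
        self.priors = study_priors


def init_state(dataset: MetaDataset, priors: PriorSpec, seed: int,
               operon_mode: bool = False) -> ChainState:
    """Initialise latent means at empirical averages, variances at their
    prior scales, indicators at zero and p at its prior mean."""
    if len(priors.studies) != dataset.n_studies:
        raise ValueError("one StudyPriors per study is required")
    rng = np.random.default_rng(seed)
    J, G = dataset.n_studies, dataset.n_genes
    omega: list[np.ndarray | None] = []
    mu = []
    theta = np.zeros((J, G))
    for j, study in enumerate(dataset.studies):
        if study.platform == OLIGO:
            counts = study.mask.sum(axis=3)
            w = np.divide(
                (study.values * study.mask).sum(axis=3), counts,
                out=np.zeros(counts.shape), where=counts > 0,
            )
            omega.append(w)
            slide_vals, slide_mask = w, counts > 0
        else:
            omega.append(None)
            slide_vals, slide_mask = study.values, study.mask
        n_slides = slide_mask.sum(axis=2)
        m = np.divide(
            (slide_vals * slide_mask).sum(axis=2), n_slides,
            out=np.zeros(n_slides.shape), where=n_slides > 0,
        )
        mu.append(m)
        theta[j] = m.mean(axis=1)
    xi = sigma2_op = None
    indicator = np.zeros(G, dtype=np.int8)
    if operon_mode:
        units = dataset.units
        if units is None:
            raise ValueError("operon model requires a unit map on the dataset")
        U = units.n_units
        xi = np.zeros((J, U))
        for j in range(J):
            xi[j] = np.bincount(
                units.unit_of_gene, weights=theta[j], minlength=U
            ) / units.unit_sizes
        sigma2_op = np.array([
            sp.operon_scale if sp.operon_scale is not None else priors.tau0_sq
            for sp in priors.studies
        ])
        indicator = np.zeros(U, dtype=np.int8)
    a, b = priors.p_prior
    return ChainState(
        omega=omega,
        mu=mu,
        theta=theta,
        xi=xi,
        sigma2_slide=np.array([sp.slide_scale for sp in priors.studies]),
        sigma2_exp=np.array([sp.exp_scale for sp in priors.studies]),
        sigma2_op=sigma2_op,
        indicator=indicator,
        p=a / (a + b),
        rng=rng,
    )


def _check_finite(state: ChainState, iteration: int) -> None:
    if not np.isfinite(state.theta).all():
        raise FloatingPointError(f"non-finite theta at iteration {iteration}")
    if not (np.isfinite(state.sigma2_slide).all() and np.isfinite(state.sigma2_exp).all()):
        raise FloatingPointError(f"non-finite variance component at iteration {iteration}")
    if not 0.0 < state.p < 1.0:
        raise FloatingPointError(f"degenerate p={state.p} at iteration {iteration}")


def _gibbs(dataset: MetaDataset, priors: PriorSpec, config: McmcConfig,
           operon_mode: bool) -> PosteriorResult:
    state = init_state(dataset, priors, config.seed, operon_mode=operon_mode)
    caches = [
        _StudyCache(study, sp) for study, sp in zip(dataset.studies, priors.studies)
    ]
    J, G = dataset.n_studies, dataset.n_genes
    rng = state.rng
    units = dataset.units if operon_mode else None
    if operon_mode:
        unit_of_gene = units.unit_of_gene
        unit_sizes = units.unit_sizes
        U = units.n_units
        is_operon_unit = unit_sizes >= 2
        is_operon_gene = is_operon_unit[unit_of_gene]
        n_operon_genes = int(is_operon_gene.sum())
        singleton_units = np.flatnonzero(~is_operon_unit)
        singleton_gene = np.array(
            [units.members_of_unit[n][0] for n in singleton_units], dtype=int
        )

    taus = np.array([priors.tau0_sq, priors.tau1_sq])
    a, b = priors.p_prior

    D_accum = np.zeros(G)
    theta_accum = np.zeros((J, G))
    p_draws = np.empty(config.n_retained)
    retained = 0

    theta_hat = np.empty((J, G))
    v_exp = np.empty(J)

    for it in range(1, config.iterations + 1):
        # probe and experiment levels
        for j, cache in enumerate(caches):
            s2_slide, s2_exp = state.sigma2_slide[j], state.sigma2_exp[j]
            if cache.platform == OLIGO:
                state.omega[j] = sample_probe_means(
                    rng, cache.probe_sum, cache.probe_count, cache.probe_var,
                    state.mu[j], s2_slide,
                )
                slide_sum = state.omega[j].sum(axis=2)
                slide_count = cache.S
            else:
                slide_sum = cache.slide_sum
                slide_count = cache.slide_count
            state.mu[j] = sample_experiment_means(
                rng, slide_sum, slide_count, s2_slide, state.theta[j], s2_exp,
            )
            theta_hat[j] = state.mu[j].mean(axis=1)
            v_exp[j] = s2_exp / cache.E

        # blocked indicator update: the unit means (theta, and xi for
        # operons) are integrated out, so the mixture densities are
        # evaluated at the data-level means with their sampling variance
        # added to tau^2; the means are then redrawn given the new I.
        if operon_mode:
            z = np.empty((J, U))
            infl = np.empty((J, U))
            for j in range(J):
                z[j] = np.bincount(
                    unit_of_gene, weights=theta_hat[j], minlength=U
                ) / unit_sizes
                infl[j] = np.where(
                    is_operon_unit,
                    (state.sigma2_op[j] + v_exp[j]) / unit_sizes,
                    v_exp[j],
                )
        else:
            z = theta_hat
            infl = v_exp[:, None]
        state.indicator = sample_indicators(
            rng, z, state.p, priors.tau0_sq, priors.tau1_sq, infl,
        )
        state.p = sample_p(
            rng, a, b, int(state.indicator.sum()), len(state.indicator),
        )

        # unit, gene and variance levels given the new indicators
        for j, cache in enumerate(caches):
            s2_exp = state.sigma2_exp[j]
            if operon_mode:
                # xi | I, mu (theta integrated out): member data-level
                # means carry variance sigma2_op + v_exp each
                mean, var = normal_posterior(
                    unit_sizes * z[j], unit_sizes,
                    state.sigma2_op[j] + v_exp[j],
                    0.0, taus[state.indicator],
                )
                xi_j = mean + np.sqrt(var) * rng.standard_normal(U)
                prior_mean = np.where(is_operon_gene, xi_j[unit_of_gene], 0.0)
                prior_var = np.where(
                    is_operon_gene,
                    state.sigma2_op[j],
                    taus[state.indicator[unit_of_gene]],
                )
            else:
                prior_mean = 0.0
                prior_var = taus[state.indicator]
            mu_sum = state.mu[j].sum(axis=1)
            state.theta[j] = sample_gene_means(
                rng, mu_sum, cache.E, s2_exp, prior_mean, prior_var,
            )
            if operon_mode:
                # singleton units: xi is pure bookkeeping, pinned to theta
                if singleton_units.size:
                    xi_j[singleton_units] = state.theta[j][singleton_gene]
                state.xi[j] = xi_j
            # variances
            sp = cache.priors
            if cache.platform == OLIGO:
                resid = state.omega[j] - state.mu[j][..., None]
                ss_slide = float((resid**2).sum())
                m_slide = cache.G * cache.E * cache.S
            else:
                resid = (cache.y - state.mu[j][..., None]) * cache.mask
                ss_slide = float((resid**2).sum())
                m_slide = cache.n_obs
            state.sigma2_slide[j] = sample_variance(
                rng, sp.slide_df, sp.slide_scale, ss_slide, m_slide,
            )
            resid_e = state.mu[j] - state.theta[j][:, None]
            state.sigma2_exp[j] = sample_variance(
                rng, sp.exp_df, sp.exp_scale, float((resid_e**2).sum()),
                cache.G * cache.E,
            )
            if operon_mode and n_operon_genes > 0:
                resid_o = (
                    state.theta[j][is_operon_gene]
                    - state.xi[j][unit_of_gene[is_operon_gene]]
                )
                state.sigma2_op[j] = sample_variance(
                    rng, sp.operon_df, sp.operon_scale,
                    float((resid_o**2).sum()), n_operon_genes,
                )

        if it % 200 == 0:
            _check_finite(state, it)
        if it > config.burn_in and (it - config.burn_in) % config.thinning == 0:
            if operon_mode:
                D_accum += state.indicator[unit_of_gene]
            else:
                D_accum += state.indicator
            theta_accum += state.theta
            p_draws[retained] = state.p
            retained += 1

    D = D_accum / retained
    result = PosteriorResult(
        genes=dataset.genes,
        D=D,
        theta_mean=theta_accum / retained,
        p_draws=p_draws[:retained],
        model="operon" if operon_mode else "independence",
        iterations=config.iterations,
        burn_in=config.burn_in,
        thinning=config.thinning,
        seed=config.seed,
        unit_of_gene=unit_of_gene.copy() if operon_mode else None,
        unit_size=unit_sizes[unit_of_gene].copy() if operon_mode else None,
    )
    return result


def run_chain(dataset: MetaDataset, priors: PriorSpec, config: McmcConfig) -> PosteriorResult:
    """Run the independence-model Gibbs chain and summarise the posterior.

    Identical data, priors and config (including seed) produce a
    bit-identical :class:`PosteriorResult`.
    """
    return _gibbs(dataset, priors, config, operon_mode=False)
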