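"""Independent numerical oracles used by the tests.

These deliberately avoid the package's conjugate closed forms: conditional
moments come from dense-grid quadrature of unnormalised densities, and
whole-posterior probabilities for micro-instances come from integrating the
marginal likelihood over the variance and mixture-weight priors with the
latent means integrated out analytically via structured Gaussian
covariances.
"""

import numpy as np
from scipy import stats


def grid_conditional_moments(data, data_var, prior_mean, prior_var,
                             lo=-20.0, hi=20.0, n=200001):
    """Mean and variance of p(m | data) ∝ prod N(y_i; m, data_var) N(m; m0, v0)
    by trapezoid quadrature on a dense grid."""
    grid = np.linspace(lo, hi, n)
    log_d = np.zeros_like(grid)
    for y in np.atleast_1d(data):
        log_d += stats.norm.logpdf(y, loc=grid, scale=np.sqrt(data_var))
    log_d += stats.norm.logpdf(grid, loc=prior_mean, scale=np.sqrt(prior_var))
    w = np.exp(log_d - log_d.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid)
    var = np.trapezoid(w * (grid - mean) ** 2, grid)
    return mean, var


def _sinvchi2_logpdf(x, df, scale):
    # scaled inverse chi-squared == inverse-gamma(df/2, df*scale/2)
    return stats.invgamma.logpdf(x, a=df / 2, scale=df * scale / 2)


def _gauss_logpdf(y, cov):
    """Batch log N(y; 0, cov) for y (d,) and cov (..., d, d)."""
    d = len(y)
    _, logdet = np.linalg.slogdet(cov)
    b = np.broadcast_to(y, cov.shape[:-2] + (d,))[..., None]
    sol = np.linalg.solve(cov, b)[..., 0]
    quad = np.einsum("...i,i->...", sol, y)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + quad)


def brute_force_independence_micro(y, slide_prior, exp_prior, tau0_sq, tau1_sq,
                                   p_prior=(1.0, 1.0), n_grid=60):
    """Prob(I_g = 1 | data) for a 1-study spotted micro-instance.

    ``y`` has shape (G, S) (one experiment).  With the latent means
    integrated out, each gene's data are jointly Gaussian with covariance
    tau^2 + sigma2_exp + sigma2_slide * I, so the posterior reduces to a
    3-D quadrature over (sigma2_slide, sigma2_exp, p).
    """
    y = np.asarray(y, dtype=float)
    G, S = y.shape
    u_s = np.linspace(np.log(1e-3), np.log(50.0), n_grid)
    u_e = np.linspace(np.log(1e-3), np.log(50.0), n_grid)
    pg = np.linspace(1e-4, 1 - 1e-4, n_grid)
    s2s = np.exp(u_s)[:, None]
    s2e = np.exp(u_e)[None, :]

    # per-gene marginal log densities under each component, (G, ns, ne)
    comp = {}
    for tau_sq, key in ((tau0_sq, 0), (tau1_sq, 1)):
        dens = np.empty((G,) + (n_grid, n_grid))
        for g in range(G):
            cov = (
                (tau_sq + s2e)[..., None, None] * np.ones((S, S))
                + s2s[..., None, None] * np.eye(S)
            )
            dens[g] = _gauss_logpdf(y[g], cov)
        comp[key] = dens

    # log prior over the variance grid (in log space; Jacobian e^u each)
    lp_var = (
        _sinvchi2_logpdf(np.exp(u_s), *slide_prior)[:, None] + u_s[:, None]
        + _sinvchi2_logpdf(np.exp(u_e), *exp_prior)[None, :] + u_e[None, :]
    )
    lp_p = stats.beta.logpdf(pg, *p_prior)

    # mixture likelihood per gene: (ns, ne, np)
    l0 = comp[0][..., None]
    l1 = comp[1][..., None]
    lp = np.log(pg)[None, None, :]
    l1p = np.log1p(-pg)[None, None, :]
    per_gene = np.logaddexp(lp + l1, l1p + l0)        # (G, ns, ne, np)
    log_joint = per_gene.sum(axis=0) + lp_var[..., None] + lp_p[None, None, :]
    w = np.exp(log_joint - log_joint.max())
    total = w.sum()

    probs = np.empty(G)
    for g in range(G):
        post_g = 1.0 / (1.0 + np.exp((l1p + l0 - lp - l1)[g]))
        probs[g] = (w * post_g).sum() / total
    return probs


def brute_force_operon_micro(y, members, slide_prior, exp_prior, operon_prior,
                             tau0_sq, tau1_sq, p_prior=(1.0, 1.0), n_grid=24):
    """Prob(I_n = 1 | data) for a 1-study spotted micro-instance with
    operon units.

    ``members`` lists the gene indices of each unit.  For a unit of K
    genes with S slides each, integrating xi, theta and mu gives a
    K*S-dimensional Gaussian with covariance
    tau^2 * J + (sigma2_op + sigma2_exp) * block-diag(J_S) + sigma2_slide * I
    (singletons: sigma2_op term absent).  Quadrature runs over
    (sigma2_slide, sigma2_exp, sigma2_op, p).
    """
    y = np.asarray(y, dtype=float)
    S = y.shape[1]
    u = np.linspace(np.log(1e-3), np.log(50.0), n_grid)
    pg = np.linspace(1e-4, 1 - 1e-4, n_grid)
    s2s, s2e, s2o = np.meshgrid(np.exp(u), np.exp(u), np.exp(u), indexing="ij")

    unit_log = {0: [], 1: []}
    for genes in members:
        K = len(genes)
        yu = y[list(genes)].ravel()
        d = K * S
        gene_block = np.kron(np.eye(K), np.ones((S, S)))
        for key, tau_sq in ((0, tau0_sq), (1, tau1_sq)):
            within = s2e if K == 1 else s2o + s2e
            cov = (
                tau_sq * np.ones((d, d))
                + within[..., None, None] * gene_block
                + s2s[..., None, None] * np.eye(d)
            )
            unit_log[key].append(_gauss_logpdf(yu, cov))
    l0 = np.stack(unit_log[0])[..., None]   # (U, ns, ne, no, 1)
    l1 = np.stack(unit_log[1])[..., None]
    lp = np.log(pg)
    l1p = np.log1p(-pg)
    per_unit = np.logaddexp(lp + l1, l1p + l0)
    lp_var = (
        _sinvchi2_logpdf(s2s, *slide_prior) + np.log(s2s)
        + _sinvchi2_logpdf(s2e, *exp_prior) + np.log(s2e)
        + _sinvchi2_logpdf(s2o, *operon_prior) + np.log(s2o)
    )
    log_joint = per_unit.sum(axis=0) + lp_var[..., None] + stats.beta.logpdf(pg, *p_prior)
    w = np.exp(log_joint - log_joint.max())
    total = w.sum()
    probs = np.empty(len(members))
    for n in range(len(members)):
        post_n = 1.0 / (1.0 + np.exp((l1p + l0 - lp - l1)[n]))
        probs[n] = (w * post_n).sum() / total
    return probs
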