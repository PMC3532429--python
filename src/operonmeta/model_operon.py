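"""Gibbs sampler for the operon (co-regulation) meta-analysis model.

Extends the independence hierarchy with one extra level: for a gene g in a
multi-gene operon unit n, theta[j,g] ~ N(xi[j,n], sigma2_op[j]), where
xi[j,n] is the operon's mean log-expression ratio in study j and
sigma2_op[j] is a common within-operon variance per study.  The
spike-and-slab mixture and the Bernoulli(p) indicator act at the unit
level: xi[j,n] ~ N(0, tau0_sq) when I[n] = 0 and N(0, tau1_sq) when
I[n] = 1.  A gene outside any operon forms a singleton unit and is treated
exactly as in the independence model (the mixture sits directly on its
theta).  Every gene in a unit inherits the unit's posterior probability of
differential expression, so D is constant within an operon by construction.

The gene-level full conditional is the familiar precision-weighted average
of the gene's own data mean and the operon mean — the borrowing-strength
mechanism that lets a weak-effect operon member be rescued by its
neighbours.
"""

from __future__ import annotations

import numpy as np

from .io_data import MetaDataset, OperonUnits
from .model_independence import (
    McmcConfig,
    PosteriorResult,
    _gibbs,
    normal_posterior,
    sample_gene_means,
)
from .priors import PriorSpec

__all__ = [
    "sample_operon_member_means",
    "sample_operon_means",
    "run_chain_operon",
]


def sample_operon_member_means(rng, mu_sum, n_exp, sigma2_exp, xi, sigma2_op):
    """Draw theta for operon-member genes: conjugate normal combining the
    gene's experiment means with the operon prior N(xi, sigma2_op)."""
    return sample_gene_means(rng, mu_sum, n_exp, sigma2_exp, xi, sigma2_op)


def sample_operon_means(rng, theta_sum, n_members, sigma2_op, tau_sq):
    """Draw xi for an operon unit: conjugate normal combining its member
    theta values (variance sigma2_op) with the mixture prior N(0, tau_sq)."""
    mean, var = normal_posterior(theta_sum, n_members, sigma2_op, 0.0, tau_sq)
    return mean + np.sqrt(var) * rng.standard_normal(np.shape(mean))


def run_chain_operon(
    dataset: MetaDataset, priors: PriorSpec, config: McmcConfig
) -> PosteriorResult:
    """Run the operon-model Gibbs chain.

    Requires ``dataset.units``; with an all-singleton unit map every update
    coincides with the independence model's.  D[g] is the posterior
    probability of the gene's unit indicator, so genes sharing an operon
    receive identical D.
    """
    if dataset.units is None:
        raise ValueError(
            "the operon model needs a unit map; build one with "
            "read_operon_map/build_operon_units or fit the independence model"
        )
    return _gibbs(dataset, priors, config, operon_mode=True)
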