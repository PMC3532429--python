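"""Data-driven elicitation of hyperparameters.

All variance components receive conjugate scaled inverse chi-squared priors
whose scale parameters are pooled from the data across all genes: the slide
scale from the spread of slide-level gene values within experiments, the
experiment scale from the spread of per-experiment gene means, and (for the
operon model) the operon scale from the within-operon spread of overall gene
means.  The probe variance of oligo studies is a plug-in constant computed
once from the data and held fixed during sampling.

The spike-and-slab mixture on unit means uses a small variance ``tau0_sq``
for non-expressed units and a large variance ``tau1_sq`` for differentially
expressed units, with a Beta prior on the mixture proportion ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import OLIGO, SPOTTED, MetaDataset, OperonUnits, StudyData

__all__ = [
    "DEFAULT_PRIOR_DF",
    "DEFAULT_TAU0_SQ",
    "DEFAULT_TAU1_SQ",
    "StudyPriors",
    "PriorSpec",
    "estimate_variance_scales",
    "estimate_probe_variance",
    "estimate_operon_scale",
    "elicit_priors",
]

#: Degrees of freedom for every scaled inverse chi-squared prior: weakly
#: informative while keeping a finite prior mean (requires df > 2).
DEFAULT_PRIOR_DF = 3.0

#: Spike variance of unit means for non-expressed units, on the
#: slide-standardized scale.
DEFAULT_TAU0_SQ = 0.01

#: Slab variance of unit means for differentially expressed units.
DEFAULT_TAU1_SQ = 4.0


@dataclass
class StudyPriors:
    """Variance hyperparameters for one study: (df, scale) pairs and the
    fixed probe variance (oligo only)."""

    slide_df: float
    slide_scale: float
    exp_df: float
    exp_scale: float
    probe_var: float | None = None  # plug-in, oligo studies only
    operon_df: float | None = None
    operon_scale: float | None = None

    def __post_init__(self) -> None:
        for name in ("slide", "exp"):
            if getattr(self, f"{name}_df") < 1:
                raise ValueError(f"{name}_df must be >= 1")
            if getattr(self, f"{name}_scale") <= 0:
                raise ValueError(f"{name}_scale must be > 0")
        if self.probe_var is not None and self.probe_var <= 0:
            raise ValueError("probe_var must be > 0")
        if self.operon_scale is not None and self.operon_scale <= 0:
            raise ValueError("operon_scale must be > 0")


@dataclass
class PriorSpec:
    """All hyperparameters for the independence and operon models."""

    studies: list[StudyPriors]
    tau0_sq: float = DEFAULT_TAU0_SQ
    tau1_sq: float = DEFAULT_TAU1_SQ
    p_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.tau0_sq <= 0 or self.tau1_sq <= 0:
            raise ValueError("mixture variances must be > 0")
        if self.tau1_sq <= self.tau0_sq:
            raise ValueError("slab variance tau1_sq must exceed spike variance tau0_sq")
        a, b = self.p_prior
        if a <= 0 or b <= 0:
            raise ValueError("Beta prior parameters must be > 0")


def _slide_level_values(data: StudyData) -> tuple[np.ndarray, np.ndarray]:
    """Per-slide gene values and their observed mask, shape (G, E, S).

    For oligo studies the slide-level value of a gene is the mean over its
    observed probes on that slide.
    """
    if data.platform == SPOTTED:
        return data.values, data.mask
    counts = data.mask.sum(axis=3)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, (data.values * data.mask).sum(axis=3), 0.0)
        means = np.divide(means, counts, out=np.zeros_like(means), where=counts > 0)
    return means, counts > 0


def _masked_var(values: np.ndarray, mask: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample variance (ddof=1) over observed entries along ``axis``;
    returns (variances, valid) with valid marking >= 2 observations."""
    n = mask.sum(axis=axis)
    total = (values * mask).sum(axis=axis)
    mean = np.divide(total, n, out=np.zeros_like(total, dtype=float), where=n > 0)
    dev = (values - np.expand_dims(mean, axis)) * mask
    ss = (dev**2).sum(axis=axis)
    var = np.divide(ss, n - 1, out=np.zeros_like(ss, dtype=float), where=n > 1)
    return var, n >= 2


def estimate_variance_scales(
    data: StudyData, default_exp_scale: float | None = None
) -> tuple[float, float]:
    """Pool slide- and experiment-level variance scales from all genes.

    Returns ``(slide_scale, exp_scale)``: the mean over (gene, experiment)
    of the within-experiment sample variance of slide values, and the mean
    over genes of the between-experiment sample variance of per-experiment
    gene means.  With a single experiment the experiment scale falls back to
    ``default_exp_scale`` (if given) with a warning.
    """
    slide_vals, slide_mask = _slide_level_values(data)
    var_s, valid_s = _masked_var(slide_vals, slide_mask, axis=2)
    if not valid_s.any():
        raise ValueError("no (gene, experiment) cell has >= 2 observed slides")
    slide_scale = float(var_s[valid_s].mean())
    if slide_scale <= 0:
        raise ValueError("degenerate scale: slide values identical within experiments")

    n_slides = slide_mask.sum(axis=2)
    exp_means = np.divide(
        (slide_vals * slide_mask).sum(axis=2),
        n_slides,
        out=np.zeros((data.n_genes, data.n_experiments)),
        where=n_slides > 0,
    )
    var_e, valid_e = _masked_var(exp_means, n_slides > 0, axis=1)
    if not valid_e.any():
        if default_exp_scale is not None:
            import logging

            logging.getLogger(__name__).warning(
                "study %s has a single experiment; using default experiment "
                "scale %.4g", data.study_id, default_exp_scale,
            )
            return slide_scale, float(default_exp_scale)
        raise ValueError("fewer than 2 experiments; cannot pool an experiment scale")
    exp_scale = float(var_e[valid_e].mean())
    if exp_scale <= 0:
        raise ValueError("degenerate scale: experiment means identical for every gene")
    return slide_scale, exp_scale


def estimate_probe_variance(data: StudyData) -> float:
    """Pooled sample variance of probe values around their slide mean.

    Pools squared deviations of each observed probe from its
    (gene, experiment, slide) probe mean over the whole study:
    ``sum of SS / sum of (B_ges - 1)``.
    """
    if data.platform != OLIGO:
        raise ValueError("probe variance is defined for oligo studies only")
    counts = data.mask.sum(axis=3)
    if not (counts >= 2).any():
        raise ValueError("no (gene, slide) cell has >= 2 observed probes")
    total = (data.values * data.mask).sum(axis=3)
    mean = np.divide(total, counts, out=np.zeros_like(total), where=counts > 0)
    dev = (data.values - mean[..., None]) * data.mask
    ss = float((dev**2).sum())
    dof = float(np.clip(counts - 1, 0, None).sum())
    var = ss / dof
    if var <= 0:
        raise ValueError("zero probe variance: probes identical within every slide")
    return var


def estimate_operon_scale(data: StudyData, units: OperonUnits) -> float:
    """Mean within-operon sample variance of overall gene means.

    Each gene's overall mean log-ratio (over all observed entries) is
    computed; the scale is the average over multi-gene operons of the sample
    variance of member means.  Singletons contribute nothing.
    """
    if units.n_operons == 0:
        raise ValueError(
            "no multi-gene operon in the unit map; the operon model is not "
            "applicable — use the independence model instead"
        )
    flat = data.values.reshape(data.n_genes, -1)
    flat_mask = data.mask.reshape(data.n_genes, -1)
    n_obs = flat_mask.sum(axis=1)
    gene_means = np.divide(
        (flat * flat_mask).sum(axis=1), n_obs,
        out=np.zeros(data.n_genes), where=n_obs > 0,
    )
    variances = [
        gene_means[members].var(ddof=1)
        for members in units.members_of_unit
        if len(members) >= 2
    ]
    scale = float(np.mean(variances))
    if scale <= 0:
        raise ValueError("zero operon scale: operon members share identical means")
    return scale


def elicit_priors(
    dataset: MetaDataset,
    tau0_sq: float = DEFAULT_TAU0_SQ,
    tau1_sq: float = DEFAULT_TAU1_SQ,
    p_prior: tuple[float, float] = (1.0, 1.0),
    prior_df: float = DEFAULT_PRIOR_DF,
    default_exp_scale: float | None = 0.25,
) -> PriorSpec:
    """Derive a full :class:`PriorSpec` from the data.

    Variance scales are pooled per study; operon scales are computed only
    when the dataset carries a unit map with at least one multi-gene operon.
    """
    study_priors = []
    for study in dataset.studies:
        slide_scale, exp_scale = estimate_variance_scales(
            study, default_exp_scale=default_exp_scale
        )
        probe_var = estimate_probe_variance(study) if study.platform == OLIGO else None
        operon_df = operon_scale = None
        if dataset.units is not None and dataset.units.n_operons > 0:
            operon_df = prior_df
            operon_scale = estimate_operon_scale(study, dataset.units)
        study_priors.append(
            StudyPriors(
                slide_df=prior_df,
                slide_scale=slide_scale,
                exp_df=prior_df,
                exp_scale=exp_scale,
                probe_var=probe_var,
                operon_df=operon_df,
                operon_scale=operon_scale,
            )
        )
    return PriorSpec(
        studies=study_priors, tau0_sq=tau0_sq, tau1_sq=tau1_sq, p_prior=p_prior
    )
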