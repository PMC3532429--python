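"""Seeded synthetic-data generator for multi-platform meta-analysis studies.

The generator mirrors the hierarchical model: differential-expression (DE)
status is assigned at the unit level (whole operons are DE or not), DE
units draw a unit mean from a wide normal and null units from a narrow one,
operon members scatter around their unit mean, and each study then layers
experiment, slide and (for oligo designs) probe noise on top before every
slide is standardized to zero mean and unit SD.

The canonical scenarios simulate 3,000 genes with a configurable fraction
of DE genes (5%, 10% or 25% in the standard settings), a Geobacter-like
operon structure (~55% of genes in operons of 2-6 genes), and either two
studies (one spotted-array design, one oligo design) or five studies (the
two-study pair plus one more spotted and two more oligo designs with
jittered noise levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .inference_metrics import TruthSet
from .io_data import (
    OLIGO,
    SPOTTED,
    MetaDataset,
    OperonUnits,
    StudyData,
    standardize_slides,
)

__all__ = [
    "StudyDesign",
    "OperonConfig",
    "SimScenario",
    "SimTruth",
    "TWO_STUDY_DESIGNS",
    "FIVE_STUDY_DESIGNS",
    "simulate_operon_structure",
    "simulate_truth",
    "simulate_study",
    "simulate_scenario",
    "simulate_paper_scenario",
]


@dataclass(frozen=True)
class StudyDesign:
    """Shape of one study: platform and replication levels."""

    platform: str
    n_experiments: int
    n_slides: int
    n_probes: int = 1
    noise_jitter: float = 1.0  # multiplies exp/slide/probe SDs

    def __post_init__(self) -> None:
        if self.platform not in (SPOTTED, OLIGO):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.platform == SPOTTED and self.n_probes != 1:
            raise ValueError("spotted designs have no probe axis")


@dataclass(frozen=True)
class OperonConfig:
    """Operon-size distribution: geometric on {min_size..max_size},
    truncated, filling genes until ``operon_fraction`` of the genome lies
    in operons."""

    operon_fraction: float = 0.55
    min_size: int = 2
    max_size: int = 6
    geometric_p: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.operon_fraction <= 1.0:
            raise ValueError("operon_fraction must lie in [0, 1]")
        if not 2 <= self.min_size <= self.max_size:
            raise ValueError("need 2 <= min_size <= max_size")


#: Spotted study: 3 experiments x 2 slides; oligo study: 2 experiments x
#: 2 slides x 4 probes.
TWO_STUDY_DESIGNS = (
    StudyDesign(SPOTTED, n_experiments=3, n_slides=2),
    StudyDesign(OLIGO, n_experiments=2, n_slides=2, n_probes=4),
)

#: The two-study pair plus one spotted and two oligo designs whose noise
#: levels sit somewhat outside the base range (+/- 30% jitter).
FIVE_STUDY_DESIGNS = TWO_STUDY_DESIGNS + (
    StudyDesign(SPOTTED, n_experiments=3, n_slides=2, noise_jitter=1.3),
    StudyDesign(OLIGO, n_experiments=2, n_slides=2, n_probes=4, noise_jitter=0.7),
    StudyDesign(OLIGO, n_experiments=2, n_slides=2, n_probes=4, noise_jitter=1.3),
)


@dataclass(frozen=True)
class SimScenario:
    """All simulation settings.  SDs are on the pre-standardization scale."""

    n_genes: int = 3000
    p_s: float = 0.05
    operon_config: OperonConfig = field(default_factory=OperonConfig)
    study_designs: tuple[StudyDesign, ...] = TWO_STUDY_DESIGNS
    effect_sd: float = 2.0   # SD of DE unit means; sqrt of the default slab tau1_sq
    null_sd: float = 0.1     # SD of null unit means; sqrt of the default spike tau0_sq
    operon_sd: float = 0.2   # gene scatter around the operon mean
    exp_sd: float = 0.5
    slide_sd: float = 0.5
    probe_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        for name in ("effect_sd", "null_sd", "operon_sd", "exp_sd", "slide_sd", "probe_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.study_designs:
            raise ValueError("at least one study design is required")


@dataclass
class SimTruth:
    """Ground truth of one simulation replicate."""

    unit_de: np.ndarray          # (U,) bool
    xi: np.ndarray               # (J,U) simulated unit means per study
    theta: np.ndarray            # (J,G) simulated gene means per study
    truth: TruthSet              # genes of DE units

    @property
    def n_true(self) -> int:
        return len(self.truth.true_genes)


def simulate_operon_structure(
    n_genes: int, config: OperonConfig, seed: int | np.random.Generator
) -> OperonUnits:
    """Draw an operon partition of ``n_genes`` genes.

    Operon sizes are drawn from a truncated geometric distribution on
    {min_size..max_size} until the target in-operon gene fraction is
    reached; leftover genes become singletons.  Gene indices are assigned
    to operons in order, matching the chromosomal-adjacency origin of
    operons.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes_support = np.arange(config.min_size, config.max_size + 1)
    if sizes_support[0] > n_genes:
        raise ValueError("operon min_size exceeds the number of genes")
    pmf = config.geometric_p * (1 - config.geometric_p) ** (sizes_support - config.min_size)
    pmf /= pmf.sum()
    target = int(round(config.operon_fraction * n_genes))
    sizes: list[int] = []
    placed = 0
    while placed < target:
        k = int(rng.choice(sizes_support, p=pmf))
        if placed + k > n_genes:
            break
        # stop once adding the operon would overshoot the target by more
        # than it undershoots
        if placed + k - target > target - placed:
            break
        sizes.append(k)
        placed += k
    members_of_unit = []
    cursor = 0
    for k in sizes:
        members_of_unit.append(np.arange(cursor, cursor + k))
        cursor += k
    for g in range(cursor, n_genes):
        members_of_unit.append(np.array([g]))
    unit_of_gene = np.empty(n_genes, dtype=int)
    for n, members in enumerate(members_of_unit):
        unit_of_gene[members] = n
    return OperonUnits(unit_of_gene=unit_of_gene, members_of_unit=members_of_unit)


def simulate_truth(
    units: OperonUnits, scenario: SimScenario, rng: np.random.Generator
) -> SimTruth:
    """Assign DE status at unit level and draw unit and gene means.

    Each unit is DE with probability ``p_s``; per study, DE units draw
    xi ~ N(0, effect_sd^2) and null units xi ~ N(0, null_sd^2).  Operon
    members draw theta ~ N(xi, operon_sd^2); singleton genes take theta =
    xi.  Genes in one operon therefore share DE status by construction.
    """
    U = units.n_units
    J = len(scenario.study_designs)
    G = units.n_genes
    unit_de = rng.random(U) < scenario.p_s
    sd = np.where(unit_de, scenario.effect_sd, scenario.null_sd)
    xi = sd * rng.standard_normal((J, U))
    theta = np.empty((J, G))
    sizes = units.unit_sizes[units.unit_of_gene]
    gene_xi = xi[:, units.unit_of_gene]
    scatter = scenario.operon_sd * rng.standard_normal((J, G))
    theta = np.where(sizes >= 2, gene_xi + scatter, gene_xi)
    true_genes = np.flatnonzero(unit_de[units.unit_of_gene])
    return SimTruth(unit_de=unit_de, xi=xi, theta=theta, truth=TruthSet(true_genes))


def simulate_study(
    theta_j: np.ndarray,
    design: StudyDesign,
    scenario: SimScenario,
    rng: np.random.Generator,
    study_id: str = "sim",
) -> StudyData:
    """Layer experiment/slide(/probe) noise on gene means and standardize.

    Spotted: y[g,e,s] = theta + exp noise[g,e] + slide noise[g,e,s].
    Oligo adds probe noise[g,e,s,b] beneath the slide level.  Each slide is
    then standardized to zero mean and unit sample SD.
    """
    G = len(theta_j)
    E, S, B = design.n_experiments, design.n_slides, design.n_probes
    exp_noise = design.noise_jitter * scenario.exp_sd * rng.standard_normal((G, E))
    slide_noise = design.noise_jitter * scenario.slide_sd * rng.standard_normal((G, E, S))
    base = theta_j[:, None, None] + exp_noise[:, :, None] + slide_noise
    if design.platform == SPOTTED:
        values = base
        mask = np.ones_like(values, dtype=bool)
    else:
        probe_noise = (
            design.noise_jitter * scenario.probe_sd * rng.standard_normal((G, E, S, B))
        )
        values = base[..., None] + probe_noise
        mask = np.ones_like(values, dtype=bool)
    genes = [f"g{i:05d}" for i in range(G)]
    study = StudyData(
        study_id=study_id, platform=design.platform, genes=genes,
        values=values, mask=mask,
    )
    return standardize_slides(study)


def simulate_scenario(scenario: SimScenario) -> tuple[MetaDataset, SimTruth]:
    """Generate a full multi-study dataset plus ground truth from one seed."""
    rng = np.random.default_rng(scenario.seed)
    units = simulate_operon_structure(scenario.n_genes, scenario.operon_config, rng)
    sim_truth = simulate_truth(units, scenario, rng)
    studies = [
        simulate_study(sim_truth.theta[j], design, scenario, rng,
                       study_id=f"study{j + 1}-{design.platform}")
        for j, design in enumerate(scenario.study_designs)
    ]
    return MetaDataset(studies=studies, units=units), sim_truth


def simulate_paper_scenario(
    name: str, p_s: float, seed: int, n_genes: int = 3000, **overrides
) -> tuple[MetaDataset, SimTruth]:
    """Convenience wrapper for the two canonical designs.

    ``name`` is ``"two_study"`` (one spotted + one oligo study) or
    ``"five_study"`` (that pair plus one spotted and two oligo studies with
    jittered noise levels).
    """
    designs = {"two_study": TWO_STUDY_DESIGNS, "five_study": FIVE_STUDY_DESIGNS}
    if name not in designs:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(designs)}")
    scenario = SimScenario(
        n_genes=n_genes, p_s=p_s, study_designs=designs[name], seed=seed, **overrides
    )
    return simulate_scenario(scenario)
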