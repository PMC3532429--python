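"""Reading, validation and standardization of expression tables and operon maps.

Two array platforms are supported.  Spotted (two-color cDNA) arrays yield one
normalized log-expression ratio per gene per slide, organised as replicate
slides within repeated experiments; the in-memory tensor is indexed
``[gene, experiment, slide]``.  In-situ synthesized oligonucleotide (ISO)
arrays additionally carry up to four probes per gene on each slide; their
tensor is indexed ``[gene, experiment, slide, probe]``.  Missing cells are
permitted and tracked with a boolean mask; every downstream sum or count uses
observed entries only.

The canonical on-disk format is a long-format delimited table with header
columns ``gene  experiment  slide  [probe]  value``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SPOTTED",
    "OLIGO",
    "MAX_PROBES",
    "StudyData",
    "OperonUnits",
    "MetaDataset",
    "read_study",
    "write_study",
    "standardize_slides",
    "read_operon_map",
    "build_operon_units",
    "build_meta_dataset",
]

logger = logging.getLogger(__name__)

SPOTTED = "spotted"
OLIGO = "oligo"

#: ISO arrays characterise each gene by at most four probes per slide.
MAX_PROBES = 4

_REQUIRED_COLS = ("gene", "experiment", "slide", "value")


@dataclass
class StudyData:
    """One study's observed log-ratio tensor with a missing-value mask.

    ``values`` is indexed ``[g, e, s]`` for spotted arrays and
    ``[g, e, s, b]`` for oligo arrays; entries where ``mask`` is False are
    unobserved and their ``values`` entries are zero-filled placeholders.
    """

    study_id: str
    platform: str
    genes: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.platform not in (SPOTTED, OLIGO):
            raise ValueError(f"unknown platform {self.platform!r}")
        expected_ndim = 3 if self.platform == SPOTTED else 4
        if self.values.ndim != expected_ndim:
            raise ValueError(
                f"{self.platform} tensor must have {expected_ndim} axes, "
                f"got {self.values.ndim}"
            )
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("gene list length does not match tensor")
        if self.platform == OLIGO and self.values.shape[3] > MAX_PROBES:
            raise ValueError(
                f"oligo probe axis has size {self.values.shape[3]}; "
                f"at most {MAX_PROBES} probes per gene are supported"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    @property
    def n_slides(self) -> int:
        return self.values.shape[2]

    def slide_view(self) -> np.ndarray:
        """Values reshaped so that axis 0 and 1 index (experiment, slide)."""
        return np.moveaxis(self.values, (1, 2), (0, 1))

    def subset_genes(self, indices: np.ndarray) -> "StudyData":
        return replace(
            self,
            genes=[self.genes[i] for i in indices],
            values=self.values[indices],
            mask=self.mask[indices],
        )


@dataclass
class OperonUnits:
    """Partition of the gene universe into operons and singleton units.

    Units are indexed ``0 .. n_units-1``; the first ``n_operons`` units have
    at least two member genes (operons), the remaining ``n_singletons`` are
    single genes not assigned to any operon.
    """

    unit_of_gene: np.ndarray  # (G,) int, unit index per gene
    members_of_unit: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.zeros(len(self.unit_of_gene), dtype=int)
        for n, members in enumerate(self.members_of_unit):
            if not np.all(self.unit_of_gene[members] == n):
                raise ValueError("unit_of_gene inconsistent with members_of_unit")
            counts[members] += 1
        if not np.all(counts == 1):
            raise ValueError("units must partition the gene set")
        sizes = self.unit_sizes
        is_singleton = sizes == 1
        if is_singleton.any() and (~is_singleton).any():
            if np.flatnonzero(is_singleton).min() < np.flatnonzero(~is_singleton).max():
                raise ValueError("operon units must precede singleton units")

    @property
    def n_units(self) -> int:
        return len(self.members_of_unit)

    @property
    def unit_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members_of_unit], dtype=int)

    @property
    def n_operons(self) -> int:
        return int(np.sum(self.unit_sizes >= 2))

    @property
    def n_singletons(self) -> int:
        return self.n_units - self.n_operons

    @property
    def n_genes(self) -> int:
        return len(self.unit_of_gene)


@dataclass
class MetaDataset:
    """Multiple studies over one shared, ordered gene universe."""

    studies: list[StudyData]
    units: OperonUnits | None = None

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("at least one study is required")
        genes = self.studies[0].genes
        for study in self.studies[1:]:
            if study.genes != genes:
                raise ValueError("all studies must share one ordered gene list")
        if self.units is not None and self.units.n_genes != len(genes):
            raise ValueError("operon units cover a different gene universe")

    @property
    def genes(self) -> list[str]:
        return self.studies[0].genes

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def read_study(
    path,
    platform: str,
    study_id: str | None = None,
    sep: str = "\t",
) -> StudyData:
    """Assemble a :class:`StudyData` tensor from a long-format table.

    The table must carry columns ``gene, experiment, slide, value`` plus
    ``probe`` for oligo studies.  Cells absent from the table are masked as
    unobserved; a duplicated (gene, experiment, slide[, probe]) cell is an
    error.
    """
    if platform not in (SPOTTED, OLIGO):
        raise ValueError(f"unknown platform {platform!r}")
    df = pd.read_csv(path, sep=sep, dtype={"gene": str}, float_precision="round_trip")
    required = list(_REQUIRED_COLS) + (["probe"] if platform == OLIGO else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if platform == SPOTTED and "probe" in df.columns:
        raise ValueError("probe column present for spotted platform")
    if df["gene"].isna().any() or (df["gene"].str.len() == 0).any():
        raise ValueError("empty gene identifier")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), "value"].iloc[0]
        raise ValueError(f"non-numeric value {bad!r}")

    keys = ["gene", "experiment", "slide"] + (["probe"] if platform == OLIGO else [])
    if df.duplicated(subset=keys).any():
        dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
        raise ValueError(
            "duplicate observation for cell "
            + ", ".join(f"{k}={dup[k]}" for k in keys)
        )

    genes = sorted(df["gene"].unique())
    axes = [genes] + [sorted(df[k].unique()) for k in keys[1:]]
    shape = tuple(len(a) for a in axes)
    if platform == OLIGO and shape[3] > MAX_PROBES:
        raise ValueError(
            f"{shape[3]} probe levels found; at most {MAX_PROBES} are supported"
        )
    lookups = [{label: i for i, label in enumerate(axis)} for axis in axes]
    idx = tuple(
        df[k].map(lookup).to_numpy() for k, lookup in zip(keys, lookups)
    )
    tensor = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    tensor[idx] = values.to_numpy(dtype=float)
    mask[idx] = True
    return StudyData(
        study_id=study_id or str(path),
        platform=platform,
        genes=genes,
        values=tensor,
        mask=mask,
    )


def write_study(data: StudyData, path, sep: str = "\t") -> None:
    """Write a study tensor back to the canonical long-format table."""
    obs = np.argwhere(data.mask)
    records = {
        "gene": [data.genes[i] for i in obs[:, 0]],
        "experiment": obs[:, 1],
        "slide": obs[:, 2],
    }
    if data.platform == OLIGO:
        records["probe"] = obs[:, 3]
    records["value"] = data.values[tuple(obs.T)]
    # default float formatting uses shortest round-trip repr, so the
    # tensor survives write/read bit-exactly
    pd.DataFrame(records).to_csv(path, sep=sep, index=False)


def standardize_slides(data: StudyData) -> StudyData:
    """Standardize each slide to zero mean and unit sample SD.

    A slide pools all genes (and, for oligo studies, all probes) hybridised
    to it.  Uses the n-1 sample SD; a slide whose observed values are
    constant is rejected.
    """
    values = data.values.copy()
    for e in range(data.n_experiments):
        for s in range(data.n_slides):
            m = data.mask[:, e, s]
            obs = values[:, e, s][m]
            if obs.size == 0:
                raise ValueError(f"slide (experiment={e}, slide={s}) has no observations")
            if obs.size < 2:
                raise ValueError(
                    f"slide (experiment={e}, slide={s}) has fewer than 2 observations"
                )
            sd = obs.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance slide (experiment={e}, slide={s})")
            values[:, e, s][m] = (obs - obs.mean()) / sd
    values[~data.mask] = 0.0
    return replace(data, values=values)


def build_operon_units(
    membership: dict[str, str],
    genes: list[str],
    on_unknown_gene: str = "error",
) -> OperonUnits:
    """Build :class:`OperonUnits` from a gene → operon-label mapping.

    Labels covering a single listed gene are demoted to singletons; genes
    absent from the mapping become singletons.  ``on_unknown_gene`` controls
    what happens when the mapping names a gene outside ``genes``:
    ``"error"`` (default) raises, ``"drop"`` warns and ignores it.
    """
    index_of = {g: i for i, g in enumerate(genes)}
    by_label: dict[str, list[int]] = {}
    for gene, label in membership.items():
        if gene not in index_of:
            if on_unknown_gene == "drop":
                logger.warning("operon map gene %s not in expression data; dropped", gene)
                continue
            raise ValueError(f"operon map gene {gene!r} not in the expression gene universe")
        by_label.setdefault(label, []).append(index_of[gene])

    operons = sorted(
        (sorted(members) for members in by_label.values() if len(members) >= 2),
        key=lambda m: m[0],
    )
    in_operon = np.zeros(len(genes), dtype=bool)
    members_of_unit: list[np.ndarray] = []
    for members in operons:
        members_of_unit.append(np.array(members, dtype=int))
        in_operon[members] = True
    for g in range(len(genes)):
        if not in_operon[g]:
            members_of_unit.append(np.array([g], dtype=int))
    unit_of_gene = np.empty(len(genes), dtype=int)
    for n, members in enumerate(members_of_unit):
        unit_of_gene[members] = n
    return OperonUnits(unit_of_gene=unit_of_gene, members_of_unit=members_of_unit)


def read_operon_map(
    path,
    genes: list[str],
    sep: str = "\t",
    on_unknown_gene: str = "error",
) -> OperonUnits:
    """Read a two-column ``gene  operon`` table into :class:`OperonUnits`."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = list(df.columns[:2])
    if len(cols) < 2:
        raise ValueError("operon map needs two columns: gene, operon")
    dup = df.duplicated(subset=cols[0], keep=False)
    if dup.any():
        sub = df[dup]
        if (sub.groupby(cols[0])[cols[1]].nunique() > 1).any():
            gene = sub.iloc[0][cols[0]]
            raise ValueError(f"ambiguous membership: gene {gene!r} listed under two operons")
        df = df.drop_duplicates(subset=cols[0])
    membership = dict(zip(df[cols[0]], df[cols[1]]))
    return build_operon_units(membership, genes, on_unknown_gene=on_unknown_gene)


def build_meta_dataset(
    studies: list[StudyData],
    units: OperonUnits | None = None,
    operon_map: dict[str, str] | None = None,
) -> MetaDataset:
    """Align studies on the intersection of their gene universes.

    Genes absent from any study are dropped with a logged warning, mirroring
    the practice of analysing only genes with expression in every study.
    ``units`` must already refer to the aligned universe; pass ``operon_map``
    (gene → label) instead to build units after alignment.
    """
    common = set(studies[0].genes)
    for study in studies[1:]:
        common &= set(study.genes)
    if not common:
        raise ValueError("no genes shared by all studies")
    genes = sorted(common)
    aligned = []
    for study in studies:
        dropped = len(study.genes) - len(genes)
        if dropped:
            logger.warning(
                "study %s: dropping %d genes outside the common universe",
                study.study_id, dropped,
            )
        index_of = {g: i for i, g in enumerate(study.genes)}
        aligned.append(study.subset_genes(np.array([index_of[g] for g in genes])))
    if units is None and operon_map is not None:
        units = build_operon_units(operon_map, genes, on_unknown_gene="drop")
    return MetaDataset(studies=aligned, units=units)
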