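import numpy as np
import pytest

from operonmeta.io_data import OLIGO, SPOTTED, MetaDataset, StudyData, build_operon_units


def make_spotted(values, mask=None, study_id="s1", genes=None):
    """StudyData from a (G, E, S) array."""
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return StudyData(study_id=study_id, platform=SPOTTED, genes=genes,
                     values=values, mask=mask)


def make_oligo(values, mask=None, study_id="s2", genes=None):
    """StudyData from a (G, E, S, B) array."""
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return StudyData(study_id=study_id, platform=OLIGO, genes=genes,
                     values=values, mask=mask)


@pytest.fixture
def tiny_spotted():
    rng = np.random.default_rng(7)
    return make_spotted(rng.normal(size=(5, 2, 3)))


@pytest.fixture
def micro_dataset():
    """1 spotted study, 2 genes, 1 experiment, 2 slides — small enough for
    brute-force posterior integration."""
    values = np.array([[[1.6, 2.1]], [[0.1, -0.3]]])  # gene 0 strong, gene 1 null
    study = make_spotted(values)
    return MetaDataset(studies=[study])


def all_singleton_units(n_genes):
    return build_operon_units({}, [f"g{i}" for i in range(n_genes)])
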