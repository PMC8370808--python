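import numpy as np
import pandas as pd
import pytest

from phylosym import synthetic_data as sd
from phylosym.io_formats import (
    DIET_CATEGORIES,
    METADATA_COLUMNS,
    RANKS,
    DietTable,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
)


def make_feature_table(counts, feature_ids=None, sample_ids=None, kingdom=None):
    counts = np.asarray(counts)
    feature_ids = feature_ids or [f"f{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=feature_ids, columns=sample_ids), kingdom)


def make_metadata(sample_ids, **overrides):
    data = {c: ["x"] * len(sample_ids) for c in METADATA_COLUMNS}
    data.update(overrides)
    return SampleMetadata(pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")))


def make_taxonomy(feature_ids, lineages=None):
    if lineages is None:
        lineages = [["k", "p", "c", "o", "fam", f"g{i}"] for i in range(len(feature_ids))]
    return TaxonomyTable(
        pd.DataFrame(lineages, index=pd.Index(feature_ids, name="feature_id"), columns=list(RANKS))
    )


def make_diet(species, proportions=None):
    if proportions is None:
        proportions = np.full((len(species), len(DIET_CATEGORIES)), 10.0)
    return DietTable(
        pd.DataFrame(
            proportions, index=pd.Index(species, name="species"), columns=list(DIET_CATEGORIES)
        )
    )


@pytest.fixture(scope="session")
def dataset():
    """Moderate simulated dataset with phylogenetic signal and coupling."""
    cfg = sd.SimulationConfig(
        n_species=8,
        samples_per_species=4,
        n_features_per_kingdom=150,
        depth=800,
        phylo_strength=1.0,
        coupling=0.7,
        sigma_within=0.4,
        batch_effect_size=0.3,
        diet_signal=0.8,
        seed=11,
    )
    return sd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No phylogenetic signal, no coupling, no batch effects."""
    cfg = sd.SimulationConfig(
        n_species=6,
        samples_per_species=3,
        n_features_per_kingdom=40,
        depth=300,
        phylo_strength=0.0,
        coupling=0.0,
        sigma_within=0.5,
        batch_effect_size=0.0,
        seed=4,
    )
    return sd.simulate_dataset(cfg)
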