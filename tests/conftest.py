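import numpy as np
import pandas as pd
import pytest

from trait_seascape import (
    AbundanceTable,
    EnvironmentTable,
    FuzzyTraitTable,
    SeascapeScenario,
    effect_codebook,
    generate_dataset,
)

EFFECT_TRAITS = ("BM", "FT", "SD", "MB", "AF", "VP", "BT", "maxBD")


def make_fuzzy(rows: dict[str, dict[tuple[str, str], float]],
               codebook=None) -> FuzzyTraitTable:
    """Build a FuzzyTraitTable from {taxon: {(trait, modality): affinity}}."""
    cb = codebook or effect_codebook()
    traits = sorted({t for r in rows.values() for t, _ in r})
    cols = [(t, m) for t in traits for m in cb[t].modalities]
    data = pd.DataFrame(0.0, index=list(rows), columns=pd.MultiIndex.from_tuples(cols))
    for taxon, affin in rows.items():
        for key, val in affin.items():
            data.loc[taxon, key] = val
    return FuzzyTraitTable(data)


def random_effect_table(rng: np.random.Generator, n_taxa: int) -> FuzzyTraitTable:
    """Random 0/1 effect-trait table with 1-2 modalities set per trait."""
    cb = effect_codebook()
    cols = [(t, m) for t in EFFECT_TRAITS for m in cb[t].modalities]
    data = pd.DataFrame(0.0, index=[f"t{i}" for i in range(n_taxa)],
                        columns=pd.MultiIndex.from_tuples(cols))
    for i in range(n_taxa):
        for t in EFFECT_TRAITS:
            mods = cb[t].modalities
            k = 1 + (rng.random() < 0.3)
            for m in rng.choice(len(mods), size=min(k, len(mods)), replace=False):
                data.iloc[i, data.columns.get_loc((t, mods[m]))] = 1.0
    return FuzzyTraitTable(data)


@pytest.fixture(scope="session")
def linked_dataset():
    """A synthetic seascape with a strong trait-environment link."""
    sc = SeascapeScenario(n_sites=30, n_species=25, seed=2, link_strength=1.5)
    env, grid, cells, Q, labels, L = generate_dataset(sc)
    return sc, env, grid, Q, labels, L


@pytest.fixture
def toy_RLQ():
    """A tiny hand-checkable R/L/Q triple (4 sites, 3 taxa)."""
    R = EnvironmentTable(pd.DataFrame(
        {"DOX": [300.0, 200.0, 100.0, 50.0], "Depth": [10.0, 50.0, 120.0, 180.0]},
        index=["s1", "s2", "s3", "s4"]))
    L = AbundanceTable(pd.DataFrame(
        [[10.0, 2.0, 0.0], [5.0, 5.0, 1.0], [1.0, 6.0, 4.0], [0.0, 2.0, 9.0]],
        index=["s1", "s2", "s3", "s4"], columns=["a", "b", "c"]))
    Q = make_fuzzy({
        "a": {("SD", "0"): 1.0},
        "b": {("SD", "0-5"): 1.0, ("SD", "5-15"): 1.0},
        "c": {("SD", "> 30"): 1.0},
    })
    return R, L, Q
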