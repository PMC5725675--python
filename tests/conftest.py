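import numpy as np
import pandas as pd
import pytest

import gblend as gb


@pytest.fixture(scope="session")
def toy_config():
    """Three-generation population small enough for exact oracles."""
    return gb.SimulationConfig(
        n_founders=60,
        n_generations=3,
        n_sires_per_gen=8,
        n_dams_per_gen=20,
        offspring_per_dam=3,
        n_chromosomes=2,
        markers_per_chromosome=100,
        n_qtl=40,
        hatch_week_levels=3,
        seed=1,
    )


@pytest.fixture(scope="session")
def toy_pop(toy_config):
    pop = gb.simulate_population(toy_config)
    subset = gb.split_trn_tst(pop.pedigree, 0.6, seed=2)
    pop.phenotypes["subset"] = subset.loc[pop.phenotypes["id"]].to_numpy()
    return pop


@pytest.fixture(scope="session")
def toy_A(toy_pop):
    return gb.build_A(toy_pop.pedigree)


def make_pedigree(rows):
    """Pedigree from (id, sire, dam) triples; sexes alternate, one cohort."""
    df = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    df["sex"] = np.where(np.arange(len(df)) % 2 == 0, "M", "F")
    df["generation"] = 0
    seen = {}
    for k, (i, s, d) in enumerate(zip(df["id"], df["sire"], df["dam"])):
        g = 0
        if s in seen:
            g = max(g, seen[s] + 1)
        if d in seen:
            g = max(g, seen[d] + 1)
        seen[i] = g
        df.loc[k, "generation"] = g
    df["hatch_week"] = 0
    return gb.Pedigree(df)


@pytest.fixture
def trio():
    """Two unrelated parents and one offspring."""
    ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
    ped.table.loc[0, "sex"] = "M"
    ped.table.loc[1, "sex"] = "F"
    return ped
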