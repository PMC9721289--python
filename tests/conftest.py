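import numpy as np
import pandas as pd
import pytest

from metablup.gamma import GammaMatrix, bend_gamma
from metablup.pedigree import GroupTable, Pedigree, sort_and_validate
from metablup.simulate import SimulationConfig, simulate_all


def make_pedigree(rows, groups=None):
    """rows: list of (animal, sire, dam, year, breed, country, sex, genotyped)."""
    df = pd.DataFrame(
        rows,
        columns=["animal", "sire", "dam", "birth_year", "breed", "country",
                 "sex", "genotyped"],
    )
    return sort_and_validate(Pedigree(df, groups=groups))


def random_pedigree(n, rng, groups=None, missing_rate=0.0, genotyped_from=None):
    """Random sorted pedigree of n animals over ~5 overlapping cohorts."""
    rows = []
    n_found = max(n // 5, 2)
    gids = groups.group_ids if groups is not None else []
    for i in range(1, n + 1):
        if i <= n_found:
            if gids:
                g = gids[rng.integers(len(gids))]
                sire = dam = -g
            else:
                sire = dam = 0
            year = 2000
        else:
            year = 2000 + int(5 * (i - n_found) / max(n - n_found, 1)) + 1
            lo = max(1, i - n // 2)
            sire = int(rng.integers(lo, i))
            dam = int(rng.integers(lo, i))
            if dam == sire:
                dam = 0 if not gids else -gids[0]
            if missing_rate and rng.random() < missing_rate:
                sire = -gids[rng.integers(len(gids))] if gids else 0
        genotyped = bool(genotyped_from is not None and i >= genotyped_from)
        rows.append((i, sire, dam, year, "A", "X", "F" if i % 2 else "M", genotyped))
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year",
                                     "breed", "country", "sex", "genotyped"])
    return sort_and_validate(Pedigree(df, groups=groups))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_group_table():
    return GroupTable(pd.DataFrame(dict(
        group_id=[1, 2], breed=["A", "B"], country=["X", "X"],
        year_start=[1950, 1950], year_end=[2030, 2030],
    )))


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete simulated data set shared across test modules."""
    cfg = SimulationConfig(seed=101, founders_per_mf=25,
                           offspring_per_generation=80, m_markers=400,
                           generations=5)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def small_sim_gamma(small_sim):
    g = GammaMatrix(small_sim.truth.gamma_true,
                    list(range(1, small_sim.config.n_metafounders + 1)),
                    provenance="extrapolated")
    return bend_gamma(g)
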