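"""Shared fixtures: small synthetic datasets reused across module tests."""

from collections import defaultdict

import pandas as pd
import pytest

import hostdiscrim as hd


SMALL = dict(
    n_species=6, n_medicago=3, plants_per_species=3, n_epg_vars=24,
    n_disc_compounds=2, n_acc_compounds=2, n_null_compounds=40,
    fractions=("polar",),
)


@pytest.fixture(scope="session")
def small_config():
    return hd.SyntheticConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return hd.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_dataset, small_config):
    by_plant = defaultdict(list)
    for pl in small_dataset.spectra:
        by_plant[pl.plant_id].append(pl)
    combined = [
        hd.combine_replicates(
            [hd.bin_spectrum(p, small_config.binning) for p in pls]
        )[0]
        for pls in by_plant.values()
    ]
    return hd.build_matrix(combined, fraction="polar")


@pytest.fixture(scope="session")
def small_scores(small_dataset):
    epg = small_dataset.epg
    prof = epg[["recording_id", "race", "clone", "species"]].copy()
    prof["E2_total_min"] = hd.extract_e2(epg).to_numpy()
    table = hd.summarize_profiles(prof, value_columns=["E2_total_min"])
    return hd.discrimination_acceptability(table)


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    epg = small_dataset.epg
    prof = epg[["recording_id", "race", "clone", "species"]].copy()
    prof["E2_total_min"] = hd.extract_e2(epg).to_numpy()
    return prof
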