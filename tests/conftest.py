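"""Shared fixtures: small simulated repertoires reused across test modules."""

import pandas as pd
import pytest

from xcompare import SimulationConfig, simulate_repertoire
from xcompare.airr_io import Repertoire


@pytest.fixture(scope="session")
def human_reps():
    return simulate_repertoire(SimulationConfig(preset="human", n_subjects=3,
                                                n_sequences=800, seed=101))


@pytest.fixture(scope="session")
def kymouse_reps():
    return simulate_repertoire(SimulationConfig(preset="kymouse", n_subjects=3,
                                                n_sequences=800, seed=102))


@pytest.fixture(scope="session")
def mouse_reps():
    return simulate_repertoire(SimulationConfig(preset="mouse", n_subjects=3,
                                                n_sequences=800, seed=103))


@pytest.fixture(scope="session")
def human_20k():
    return simulate_repertoire(SimulationConfig(preset="human", n_subjects=1,
                                                n_sequences=20000, seed=301))[0]


@pytest.fixture(scope="session")
def kymouse_20k():
    return simulate_repertoire(SimulationConfig(preset="kymouse", n_subjects=1,
                                                n_sequences=20000, seed=302))[0]


@pytest.fixture(scope="session")
def human_20k_unique(human_20k):
    from xcompare.airr_io import collapse_unique
    heavy = human_20k.df[human_20k.df["locus"] == "IGH"]
    return collapse_unique(human_20k.with_df(heavy))


@pytest.fixture(scope="session")
def kymouse_20k_unique(kymouse_20k):
    from xcompare.airr_io import collapse_unique
    heavy = kymouse_20k.df[kymouse_20k.df["locus"] == "IGH"]
    return collapse_unique(kymouse_20k.with_df(heavy))


def make_repertoire(rows, subject_id="s1", species="other") -> Repertoire:
    """Build a small Repertoire from a list of row dicts, filling defaults."""
    df = pd.DataFrame(rows)
    defaults = {"isotype": "IgM", "mutation_count": 0, "duplicate_count": 1,
                "v_call_ambiguous": False}
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "locus" not in df.columns:
        df["locus"] = df["v_call"].str[:3]
    if "sequence_id" not in df.columns:
        df["sequence_id"] = [f"{subject_id}_{i}" for i in range(len(df))]
    return Repertoire(subject_id=subject_id, species=species, df=df)
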