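import numpy as np
import pandas as pd
import pytest

import colipid as cl


@pytest.fixture(scope="session")
def database():
    return cl.generate_database()


@pytest.fixture(scope="session")
def species(database):
    return cl.named_species_table(database)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (116 constructs x 2 conditions x 3 replicates)."""
    return cl.simulate_study(cl.StudyConfig(seed=101))


@pytest.fixture(scope="session")
def annotated(study):
    """The study's feature table pushed through the full annotation pipeline."""
    return cl.process_feature_table(
        study.features,
        study.species,
        metadata=study.metadata,
        raw_table=study.features_raw,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def tiny_feature_table(entries, sample_ids):
    """Build a feature table from (mz, rt, {sample: value}) triples."""
    rows = []
    for mz, rt, vals in entries:
        row = {"mz": mz, "rt": rt}
        row.update({s: vals.get(s, 0.0) for s in sample_ids})
        rows.append(row)
    return pd.DataFrame(rows)
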