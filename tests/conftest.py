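import numpy as np
import pandas as pd
import pytest

from snpstring import SnpStringModel, datasets, simulate as sim


@pytest.fixture(scope="session")
def drb1_strings():
    return datasets.DRB1_IDENTIFIED


@pytest.fixture(scope="session")
def drb1_control_frequencies(drb1_strings):
    return {
        drb1_strings[k]: v / 100.0
        for k, v in datasets.DRB1_CONTROL_FREQ.items()
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Seeded null HWE cohort from the DRB1 control pool, no missing data."""
    spec = sim.drb1_spec(n_cases=300, n_controls=300, w=1.0, seed=42)
    return sim.simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_results(null_cohort):
    return SnpStringModel(null_cohort.matrix, null_cohort.manifest, orient=False).fit()


@pytest.fixture()
def tiny_matrix():
    """3 subjects x 11 SNPs, one missing call, as a GenotypeMatrix."""
    from snpstring import genotype_io as gio

    rsids = [f"rs{1000 + i}" for i in range(11)]
    codes = pd.DataFrame(
        [
            [2, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0],
            [0, 2, 2, 0, 2, 2, 0, 0, 0, 0, 0],
            [2, 0, 0, 0, 0, 0, 2, 2, 2, 2, pd.NA],
        ],
        index=pd.Index(["P1", "P2", "P3"], name="subject_id"),
        columns=rsids,
        dtype="Int64",
    )
    phen = pd.Series(["case", "control", "control"], index=codes.index, name="phenotype")
    return gio.GenotypeMatrix(codes=codes, phenotype=phen)
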