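import numpy as np
import pandas as pd
import pytest

from neuromarker import ExpressionDataset, GenotypeTable, SynthConfig
from neuromarker.pipeline import make_fixture


@pytest.fixture
def table4_counts() -> GenotypeTable:
    """Genotype counts of a 30+30 case-control SNP design (minor allele G):
    cases 2/11/17, controls 1/3/26 for mm/Mm/MM."""
    return GenotypeTable(
        snp="rs_test",
        minor="G",
        major="C",
        counts={"case": (2, 11, 17), "control": (1, 3, 26)},
    )


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3v3 log2 matrix with one exact 2-fold gene and background genes."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 0.5, size=(10, 6)),
        index=[f"G{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(6)],
    )
    values.loc["G0"] = [10.0, 10.0, 10.0, 8.0, 8.0, 8.0]
    groups = pd.Series(
        ["case"] * 3 + ["control"] * 3, index=values.columns
    )
    return ExpressionDataset(values, groups, name="tiny")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic input bundle written once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture(SynthConfig(seed=1), out)
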