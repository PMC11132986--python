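import numpy as np
import pandas as pd
import pytest

from spatmap.config import RunConfig
from spatmap.synthetic import FractionationSimSpec, simulate_fractionation
from spatmap.tables import ProteinGroupTable


@pytest.fixture(scope="session")
def small_fractionation():
    """A compact noiseless fractionation experiment (4 organelles)."""
    spec = FractionationSimSpec(
        seed=11,
        organelles=(
            ("LipidDroplet", 2.0, 1.5),
            ("ER", 9.0, 1.8),
            ("Mitochondrion", 16.0, 1.8),
            ("Cytosol", 22.0, 2.0),
        ),
        markers_per_organelle=15,
        n_single=40,
        n_dual=20,
        noise_sd=0.0,
        n_replicates=2,
    )
    return spec, simulate_fractionation(spec)


@pytest.fixture()
def config():
    return RunConfig(seed=0)


def make_table(values, sample_meta=None, **kwargs):
    """Build a ProteinGroupTable from a plain dict/DataFrame of intensities."""
    intens = pd.DataFrame(values)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "model": "M1",
                "timepoint_days": np.nan,
                "replicate": 1,
                "condition": "c",
                "fraction_index": np.arange(len(intens.columns)),
            },
            index=pd.Index(intens.columns, name="sample_id"),
        )
    return ProteinGroupTable(intens, sample_meta, **kwargs)


@pytest.fixture()
def fraction_meta():
    def build(columns, replicate=None, fraction=None):
        return pd.DataFrame(
            {
                "model": "M1",
                "timepoint_days": np.nan,
                "replicate": replicate if replicate is not None else 1,
                "condition": "pcp",
                "fraction_index": fraction if fraction is not None else np.arange(len(columns)),
            },
            index=pd.Index(columns, name="sample_id"),
        )

    return build
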