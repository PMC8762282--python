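import numpy as np
import pandas as pd
import pytest

from xfollicle import pipeline, synth
from xfollicle.expression import ExpressionSet


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic fixture bundle (written once per session)."""
    return synth.write_fixture_bundle(tmp_path_factory.mktemp("fixture"), seed=0)


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """End-to-end pipeline report on the default fixture."""
    return pipeline.demo(tmp_path_factory.mktemp("demo"), seed=0)


@pytest.fixture(scope="session")
def small_epigenome():
    """Compact epigenome fixture for network-level tests."""
    return synth.generate_epigenome(n_enh=30, n_se=8, se_cluster_size=3, seed=3)


def make_expression(values: np.ndarray, meta_rows: list[dict]) -> ExpressionSet:
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    vals = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=list(meta.index),
    )
    return ExpressionSet(vals, meta)
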