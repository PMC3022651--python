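import numpy as np
import pytest

from coexpr_meta.expression_io import ExpressionDataset


def make_dataset(
    name="toy",
    probesets=("p1", "p2"),
    samples=("s1", "s2", "s3"),
    values=((1.0, 2.0, 3.0), (4.0, 5.0, 6.0)),
    calls=None,
    gene_of=None,
):
    """Small hand-built ExpressionDataset for unit tests."""
    return ExpressionDataset(
        name=name,
        probeset_ids=tuple(probesets),
        sample_ids=tuple(samples),
        intensities=np.asarray(values, dtype=float),
        calls=None if calls is None else np.asarray(calls, dtype="U1"),
        gene_of=dict(gene_of or {}),
    )


@pytest.fixture
def toy_dataset():
    return make_dataset()


@pytest.fixture
def default_fixture():
    """One default synthetic fixture (seed 7), shared across tests."""
    from coexpr_meta.synthetic_data import SyntheticConfig, generate

    return generate(SyntheticConfig(seed=7))
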