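import numpy as np
import pandas as pd
import pytest

from ctscreen.io import ExpressionMatrix, TissueProfile
from ctscreen.simulate import BundleParams, GroundTruth, gen_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic input bundle shared by integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    path, truth = gen_bundle(outdir, BundleParams(), seed=7)
    return path, truth


@pytest.fixture()
def small_profile():
    """4 genes x 4 tissues: one testis-exclusive, one uniform, one at the
    0.9 boundary, one all-zero."""
    df = pd.DataFrame(
        {
            "testis": [5.0, 1.0, 9.0, 0.0],
            "liver": [0.0, 1.0, 1.0, 0.0],
            "lung": [0.0, 1.0, 0.0, 0.0],
            "brain": [0.0, 1.0, 0.0, 0.0],
        },
        index=["EXCL", "UNIF", "EDGE", "ZERO"],
    )
    return TissueProfile(df, source="unit")


def expr_matrix(values, genes, samples, unit="RSEM", context="T"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        unit=unit,
        context=context,
    )
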