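import numpy as np
import pandas as pd
import pytest

from metaconcord import (
    ExpressionMatrix,
    GeneratorConfig,
    MStage,
    NStage,
    SampleRecord,
    YesNoUnknown,
    generate_cohort,
)


def make_sample(
    sid,
    n="N0",
    m="M0",
    rec="no",
    adj="no",
    fu=36.0,
):
    return SampleRecord(
        sid,
        NStage(n) if n != "unknown" else NStage.UNKNOWN,
        MStage(m) if m != "unknown" else MStage.UNKNOWN,
        YesNoUnknown(rec),
        YesNoUnknown(adj),
        fu,
    )


@pytest.fixture
def small_config():
    """Scaled-down generator config for fast structural tests."""
    return GeneratorConfig(
        n_genes=300,
        n_de_genes=40,
        n_samples=100,
        n_null_loci=120,
        seed=11,
    )


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config, with_counts=False)


@pytest.fixture
def expr_2x2():
    return ExpressionMatrix(
        pd.DataFrame(
            [[4.0, 8.0], [6.0, 10.0]],
            index=["p1", "p2"],
            columns=["s1", "s2"],
        ),
        "log2_intensity",
    )
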