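import numpy as np
import pandas as pd
import pytest

from recurnet.synthetic import (
    LabeledExpressionMatrix,
    ModuleSpec,
    SimulationConfig,
    generate_expression,
)

GROUPS = ("recurrence", "non-recurrence")


def make_expr(values: np.ndarray, n1: int, n2: int, gene_prefix: str = "G"):
    """Wrap a raw array as a labelled matrix: first n1 columns recurrence."""
    n_genes, n_samples = values.shape
    assert n_samples == n1 + n2
    genes = [f"{gene_prefix}{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    group = pd.Series(
        ["recurrence"] * n1 + ["non-recurrence"] * n2, index=samples, name="group"
    )
    return LabeledExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), group=group
    )


@pytest.fixture(scope="session")
def null_expr_3v3():
    """2000 pure-noise genes, 3 vs 3 samples — the discovery design's null."""
    cfg = SimulationConfig(
        n_genes=2000, n_recurrence=3, n_nonrecurrence=3,
        n_de_up=1, n_de_down=1, de_effect=0.0, module_specs=(), seed=5,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def module_expr_40v40():
    """Differential co-expression only: two 25-gene modules (10 hubs each),
    r = 0.9 in one group and 0 in the other, no mean shifts, 40 + 40 samples."""
    cfg = SimulationConfig(
        n_genes=400, n_recurrence=40, n_nonrecurrence=40,
        n_de_up=1, n_de_down=1, de_effect=0.0,
        module_specs=(
            ModuleSpec(25, 10, 0.9, 0.0),
            ModuleSpec(25, 10, 0.0, 0.9),
        ),
        seed=21,
    )
    return generate_expression(cfg)


@pytest.fixture(scope="session")
def default_expr():
    """The default synthetic cohort (2000 genes x 80 samples)."""
    return generate_expression(SimulationConfig(seed=1))
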