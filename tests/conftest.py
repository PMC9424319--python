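import numpy as np
import pytest

import sigforge as sf


@pytest.fixture
def tiny_expression():
    """2 reference + 3 tumor samples, 2 genes, hand-checkable values."""
    # gene A reference {1, 3}: mean 2, sd sqrt(2); gene B reference {0, 2}: mean 1, sd sqrt(2)
    return sf.ExpressionMatrix(
        gene_ids=["A", "B"],
        sample_ids=["r1", "r2", "t1", "t2", "t3"],
        values=np.array([[1.0, 3.0, 2.0, 6.0, -2.0], [0.0, 2.0, 1.0, 1.0, 5.0]]),
        is_reference=np.array([True, True, False, False, False]),
    )


@pytest.fixture
def demo_cohort():
    """One demo synthetic cohort at the default study conditions."""
    return sf.simulate_cohort(sf.CohortConfig(seed=11))


@pytest.fixture
def simple_clinical():
    return sf.ClinicalTable(
        sample_ids=[f"s{i}" for i in range(8)],
        time=np.array([5.0, 8, 12, 20, 25, 30, 40, 50]),
        event=np.array([1, 1, 0, 1, 1, 0, 1, 1]),
    )
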