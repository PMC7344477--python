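import numpy as np
import pytest

from heteromir import CqMatrix, generate_cohort, preset


@pytest.fixture
def three_gene_cq() -> CqMatrix:
    """Hand-checkable 3-gene matrix: A and B differ by a constant cycle
    (V_AB = 0); C drifts one cycle per sample (V_AC = V_BC = 1)."""
    return CqMatrix.from_arrays(
        ["A", "B", "C"], ["s1", "s2", "s3"],
        [[20.0, 20.0, 20.0],
         [21.0, 21.0, 21.0],
         [20.0, 21.0, 22.0]])


@pytest.fixture
def random_cq() -> CqMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(9)]
    return CqMatrix.from_arrays(
        genes, samples, rng.uniform(18.0, 34.0, (6, 9)))


@pytest.fixture(scope="session")
def paper_like_cohort():
    return generate_cohort(preset("paper_like", seed=1))
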