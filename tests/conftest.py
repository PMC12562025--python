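import numpy as np
import pytest

from phenodiv import CohortSpec, TraitSpec, TraitTable, simulate_cohort


@pytest.fixture
def tiny_table() -> TraitTable:
    """3 genotypes x 1 trait x 2 replicates: {1,3},{5,7},{9,11}.

    By hand: genotype means 2, 6, 10; grand mean 6; SSg = 2*(16+0+16) = 64,
    QMg = 32; SSr = 2+2+2 = 6, QMr = 2; F = 16; CV% = 100*sqrt(2)/6 = 23.57.
    """
    values = np.array([[[1.0, 3.0]], [[5.0, 7.0]], [[9.0, 11.0]]])
    return TraitTable(["g1", "g2", "g3"], ["y"], 2, values)


@pytest.fixture
def two_trait_table() -> TraitTable:
    """3 genotypes x 2 traits x 2 replicates with hand-checkable residuals."""
    values = np.array(
        [
            [[1.0, 3.0], [2.0, 4.0]],
            [[5.0, 7.0], [1.0, 5.0]],
            [[9.0, 11.0], [6.0, 2.0]],
        ]
    )
    return TraitTable(["g1", "g2", "g3"], ["u", "v"], 2, values)


@pytest.fixture
def random_table() -> TraitTable:
    """8 genotypes x 3 traits x 4 replicates, moderate genetic signal."""
    spec = CohortSpec(
        G=8,
        r=4,
        traits=(
            TraitSpec("t1", 20.0, 9.0, 4.0),
            TraitSpec("t2", 5.0, 1.0, 0.5),
            TraitSpec("t3", 50.0, 25.0, 16.0),
        ),
        seed=77,
    )
    return simulate_cohort(spec)
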