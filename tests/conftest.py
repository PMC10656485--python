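import pytest

import bracedate as bd
from bracedate.synthetic import (SimulationRecipe, simulate_branch_sample,
                                 simulate_time_tree, simulate_ucln_rates)


@pytest.fixture(scope="session")
def three_tip():
    top, blt = bd.parse_newick("((A:1,B:1):1,C:2);")
    return top, blt


@pytest.fixture(scope="session")
def sixteen_tip_dataset():
    """One seeded 16-tip ground-truth dataset with pseudo-posterior."""
    rec = SimulationRecipe(seed=11)
    tree = simulate_time_tree(rec)
    clock = simulate_ucln_rates(tree, rec.clock_mean, rec.clock_sigma, 11)
    sample = simulate_branch_sample(tree, clock, rec.sample_size,
                                    rec.noise_cv, 11)
    return rec, tree, clock, sample
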