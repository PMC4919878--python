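import numpy as np
import pytest

from branchprior.treeio import BranchLengthSample, harvest_sample, parse_trees

QUARTET_NEWICK = "((A:0.1,B:0.2):0.05,C:0.3,D:0.4);"
STAR_NEWICK = "(A:0.1,B:0.2,C:0.3);"


@pytest.fixture
def quartet_sample() -> BranchLengthSample:
    """external=[0.1,0.2,0.3,0.4], internal=[0.05], T=1.05, n=5."""
    return harvest_sample(parse_trees(QUARTET_NEWICK)[0])


@pytest.fixture
def star_sample() -> BranchLengthSample:
    """3-taxon star: external=[0.1,0.2,0.3], no internal branches, T=0.6."""
    return harvest_sample(parse_trees(STAR_NEWICK)[0])


def random_sample(
    rng: np.random.Generator, s: int | None = None, m: int | None = None
) -> BranchLengthSample:
    """A random branch-length sample with positive lengths (not tree-derived)."""
    if s is None:
        s = int(rng.integers(3, 12))
    if m is None:
        m = max(s - 3, 0)
    external = rng.gamma(shape=1.0, scale=0.1, size=s) + 1e-6
    internal = rng.gamma(shape=1.0, scale=0.05, size=m) + 1e-6
    return BranchLengthSample(external, internal)
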