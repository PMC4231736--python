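import numpy as np
import pytest

from mirnaedit.readprep import Read
from mirnaedit.reference import MatureMiRNA
from mirnaedit.simulate import SimTruth, lognormal_expression


@pytest.fixture(scope="session")
def tiny_reference() -> list[MatureMiRNA]:
    """Five hand-written mature miRNAs, 19-23 nt, pairwise dissimilar."""
    return [
        MatureMiRNA("mir-a", "TACAGTCCTGAGGTACTTAGC"),
        MatureMiRNA("mir-b", "GGATCGTTACCAGACTTCGAA"),
        MatureMiRNA("mir-c", "CCTAAGGCATCATGTCAGTCCACA"),
        MatureMiRNA("mir-d", "ATGGCTCAAGTTCGGATCACG"),
        MatureMiRNA("mir-e", "TTCACAGTGGCTAAGTTCTGC"),
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_read(seq: str, rid: str = "r1") -> Read:
    return Read(id=rid, sequence=seq, quality="I" * len(seq))


@pytest.fixture(scope="session")
def small_truth(tiny_reference) -> SimTruth:
    """A miniature two-genotype experiment over the tiny reference."""
    expr = lognormal_expression(tiny_reference, seed=3, head_n=2, head_fraction=0.5)
    return SimTruth(
        mirnas=tiny_reference,
        expression={"wt": dict(expr), "adar2ko": dict(expr)},
        editing={
            # mir-a position 4 is an A (seed region); mir-c position 12 an A
            "wt": {("mir-a", 4): 0.4, ("mir-c", 12): 0.2},
            "adar2ko": {("mir-a", 4): 0.05, ("mir-c", 12): 0.2},
        },
        depth=20_000,
        seed=99,
    )
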