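import numpy as np
import pytest

from beamplicon.io import Read, TargetSite, locate_protospacer, revcomp
from beamplicon.simulate import make_demo_site

DNA = "ACGT"


def random_dna(rng, n):
    return "".join(rng.choice(list(DNA), size=n))


def perfect_read(site: TargetSite, rid: str = "r", phred: int = 40) -> Read:
    return Read(id=rid, sequence=site.amplicon,
                qualities=[phred] * len(site.amplicon))


def read_with_bases(site: TargetSite, changes: dict[int, str],
                    rid: str = "r", phred: int = 40) -> Read:
    """Amplicon-length read with protospacer-orientation base substitutions
    at the given protospacer positions."""
    seq = list(site.amplicon)
    for pos, base in changes.items():
        seq[site.positions[pos]] = base if site.strand == "+" else revcomp(base)
    return Read(id=rid, sequence="".join(seq), qualities=[phred] * len(seq))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def demo_site() -> TargetSite:
    return make_demo_site(seed=1)


@pytest.fixture(scope="session")
def plus_site() -> TargetSite:
    """Hand-built plus-strand site: protospacer with known A and C layout."""
    #            1234567890123456789 20
    protospacer = "GTACATCGATCAGTACCTAG"
    amplicon = "TTGACCGTGA" + protospacer + "AGG" + "CATTGGAACT"
    return locate_protospacer(amplicon, protospacer, "NGG", name="plus_site")


@pytest.fixture(scope="session")
def minus_site(plus_site) -> TargetSite:
    return locate_protospacer(revcomp(plus_site.amplicon),
                              plus_site.protospacer, "NGG", name="minus_site")
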