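import numpy as np
import pytest

from tz4c.locus_model import FragmentMap, GenomicInterval, Viewpoint, fragments_from_cuts
from tz4c.fourc_processing import ContactProfile
from tz4c.synthetic_data import default_sim_config


@pytest.fixture(scope="session")
def sim_cfg():
    """Default synthetic locus, master seed 0."""
    return default_sim_config(0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_map(n: int = 20, frag_len: int = 100, chrom: str = "chrT") -> FragmentMap:
    cuts = [frag_len * i for i in range(1, n)]
    return fragments_from_cuts(chrom, GenomicInterval(chrom, 0, frag_len * n), cuts)


def make_profile(
    counts,
    frag_len: int = 100,
    vp_pos: int | None = None,
    exclusion: int = 1,
    allele: str = "Hap",
) -> ContactProfile:
    counts = np.asarray(counts, dtype=np.int64)
    fmap = make_map(len(counts), frag_len)
    if vp_pos is None:
        vp_pos = frag_len * (len(counts) // 2)
    vp = Viewpoint("vp", vp_pos, exclusion)
    return ContactProfile(vp, allele, 0, fmap, counts)


@pytest.fixture
def random_map(rng):
    """Irregular fragment map of ~80 fragments."""
    bounds = np.unique(rng.integers(1, 10_000, size=80))
    cuts = bounds.tolist()
    return fragments_from_cuts("chrT", GenomicInterval("chrT", 0, 10_000), cuts)
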