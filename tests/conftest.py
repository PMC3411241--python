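import warnings

import numpy as np
import pytest

from admixscan.datatypes import GenotypeMatrix, SiteAnnotation
from admixscan.simulate import make_fixture

warnings.filterwarnings("ignore", message="skipping .* monomorphic")


def make_sites(n, cm=None, fragments=None, bp=None, region=None):
    """Hand-built annotation list for small constructed matrices."""
    sites = []
    for j in range(n):
        sites.append(SiteAnnotation(
            site_id=f"S{j:03d}",
            chromosome="chr1",
            genetic_pos=float(cm[j]) if cm is not None else float(j),
            physical_pos=int(bp[j]) if bp is not None else (j + 1) * 1000,
            region_class=region[j] if region is not None else "noncoding",
            fragment_id=fragments[j] if fragments is not None else f"F{j:03d}",
        ))
    return sites


def matrix_from_calls(calls, groups=None, **site_kwargs):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    accessions = [f"A{i:03d}" for i in range(n)]
    if groups is None:
        groups = ["other"] * n
    return GenotypeMatrix(accessions, groups, make_sites(L, **site_kwargs), calls)


@pytest.fixture(scope="session")
def tiny_sim():
    return make_fixture("tiny", seed=3)


@pytest.fixture(scope="session")
def paper_sim():
    return make_fixture("paper_like", seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
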