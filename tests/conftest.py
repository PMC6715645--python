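import warnings

import pytest

from karyokit import SimSpec
from karyokit.datasets import (
    ACCESSIONS,
    load_published_profiles,
    load_published_summary,
    load_published_types,
    published_karyotypes,
)

# Several published relative-length columns do not sum to ~100; the package
# warns about that on purpose.  Keep tests quiet about this known property of
# the fixtures while leaving other warnings visible.
warnings.filterwarnings(
    "ignore", message=".*relative lengths sum to.*", category=UserWarning
)
# Tiny synthetic complements (2n != 32/64) trip the basic-number advisory.
warnings.filterwarnings(
    "ignore", message=".*is not 16·ploidy.*", category=UserWarning
)


@pytest.fixture(scope="session")
def summary():
    return load_published_summary().set_index("accession")


@pytest.fixture(scope="session")
def all_profiles():
    return {acc: load_published_profiles(acc) for acc in ACCESSIONS}


@pytest.fixture(scope="session")
def all_printed_types():
    return {acc: load_published_types(acc) for acc in ACCESSIONS}


@pytest.fixture(scope="session")
def classified():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return published_karyotypes()


def rufescens_like_spec(**overrides) -> SimSpec:
    """A 16-pair diploid truth shaped like the S. rufescens karyotype."""
    kwargs = dict(
        n_pairs=16,
        ploidy=2,
        type_sequence=["st"] * 7 + ["sm"] * 7 + ["m"] * 2,
        heteromorphic_pair=(10, "sm", "m"),
        nor_pairs=frozenset({7, 11, 14}),
        noise_cv=0.02,
        condensation_sd=0.15,
        seed=1,
    )
    kwargs.update(overrides)
    return SimSpec(**kwargs)


@pytest.fixture
def sim_spec_factory():
    return rufescens_like_spec
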