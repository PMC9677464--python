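import warnings

import pytest

from microbin.markers import load_marker_hierarchy
from microbin.synthetic_data import (
    CommunitySpec,
    bundled_hierarchy_path,
    generate_community,
)


@pytest.fixture(scope="session")
def hierarchy():
    return load_marker_hierarchy(bundled_hierarchy_path())


@pytest.fixture(scope="session")
def small_bundle():
    """Read-only 5-genome / 3-sample community; do not mutate."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_community(
            CommunitySpec(
                n_genomes=5,
                genome_length_range=(150_000, 250_000),
                contigs_per_genome=(20, 50),
                n_samples=3,
                seed=2,
            )
        )


def make_bundle(**kwargs):
    defaults = dict(
        n_genomes=3,
        genome_length_range=(80_000, 120_000),
        contigs_per_genome=(5, 15),
        n_samples=2,
        seed=1,
    )
    defaults.update(kwargs)
    return generate_community(CommunitySpec(**defaults))
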