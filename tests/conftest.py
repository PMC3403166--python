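import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference5():
    """Five-taxon synthetic reference set: (records, taxonomy, seed rows)."""
    from pmeta.synthetic import generate_reference

    return generate_reference(n_taxa=5, seq_length=300, seed=7)


@pytest.fixture(scope="session")
def hmm5(reference5):
    from pmeta.rrna_extract import ProfileHMM

    _, _, seed_aln = reference5
    return ProfileHMM.from_seed_alignment(seed_aln, name="synth16s")


@pytest.fixture(scope="session")
def index5(reference5):
    from pmeta.rrna_map import ReferenceIndex

    records, _, _ = reference5
    return ReferenceIndex.build(records, w=16)


@pytest.fixture(scope="session")
def scheme():
    from pmeta.rrna_map import ScoringScheme

    return ScoringScheme()


@pytest.fixture(scope="session")
def abundances5():
    return [0.4, 0.25, 0.15, 0.12, 0.08]


@pytest.fixture(scope="session")
def community_spec(reference5, abundances5):
    from pmeta.synthetic import CommunitySpec

    records, taxonomy, _ = reference5
    return CommunitySpec(
        taxa=[(taxonomy.get(r.id), r.residues, a)
              for r, a in zip(records, abundances5)],
        n_reads=600,
        planted_fraction=0.5,
        substitution_rate=0.01,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_sample(community_spec):
    """600 synthetic reads, ~300 planted fragments, plus the truth table."""
    from pmeta.synthetic import generate_sample

    return generate_sample(community_spec)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20260928)
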