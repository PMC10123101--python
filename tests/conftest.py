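import numpy as np
import pytest

import ampdesign as ad
from ampdesign.fixtures import FamilySpec, make_family, make_guides
from ampdesign.guides import parse_guides


@pytest.fixture(scope="session")
def hiplex():
    return ad.preset("hiplex")


@pytest.fixture(scope="session")
def low_identity_family():
    """Four diverged paralogs (70% identity): specific design is easy."""
    return make_family(
        FamilySpec(n_genes=4, gene_length=800, pairwise_identity=0.70,
                   seed=11, family_id="lo")
    )


@pytest.fixture(scope="session")
def high_identity_family():
    """Four near-identical paralogs (99%): specific design collapses."""
    return make_family(
        FamilySpec(n_genes=4, gene_length=800, pairwise_identity=0.99,
                   seed=12, family_id="hi")
    )


@pytest.fixture(scope="session")
def single_gene(low_identity_family):
    return low_identity_family[0]


def guides_for(targets, n_per_gene=10, seed=21, tmp_path=None):
    import io

    df = make_guides(targets, n_per_gene=n_per_gene, seed=seed)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    guides, rejected = parse_guides(buf, dialect="generic", targets=targets)
    assert not rejected
    return guides


@pytest.fixture(scope="session")
def lo_guides(low_identity_family):
    return guides_for(low_identity_family)


@pytest.fixture(scope="session")
def lo_design(low_identity_family, lo_guides, hiplex):
    return ad.run_design(low_identity_family, guides=lo_guides, config=hiplex)


@pytest.fixture(scope="session")
def lo_candidates(single_gene, hiplex):
    cands, reason = ad.generate_candidates(single_gene, hiplex)
    assert reason is None
    return cands


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
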