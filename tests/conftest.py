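import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nrannot import synthetic_fixtures as fx
from nrannot.nonredundant_selector import merge_evidence


@pytest.fixture(scope="session")
def locus_fixture():
    """A mid-size redundant annotation with known winners (seed 11)."""
    hom, txn, manifest = fx.gen_locus_set(200, seed=11)
    return hom, txn, manifest


@pytest.fixture(scope="session")
def merged_fixture(locus_fixture):
    hom, txn, manifest = locus_fixture
    return merge_evidence(hom, txn), manifest


@pytest.fixture(scope="session")
def blast_fixture():
    """Planted bipartite RBH structure with all confounder classes."""
    fwd, rev, manifest = fx.gen_blast_tables(
        200, 200, rbh_fraction=0.6, seed=23, n_one_way=15, n_subthreshold=10,
        multi_hsp=True,
    )
    return fx.rows_to_hits(fwd), fx.rows_to_hits(rev), fwd, rev, manifest
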