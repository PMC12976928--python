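import numpy as np
import pytest

import tcrcontact as tc


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    return tc.generate_world(tc.WorldConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_world):
    return tc.generate_dataset(small_world, n_pos=30, neg_ratio=4, seed=70)


@pytest.fixture(scope="session")
def small_store(small_world, small_dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("store") / "store.h5"
    seqs = tc.unique_sequences(small_dataset.records)
    return tc.build_store(seqs, tc.synthetic_provider(small_world), path)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_records():
    """A tiny hand-built positive set spanning three epitopes."""
    mk = lambda a, b, e: tc.TriadRecord(cdr3a=a, cdr3b=b, peptide=e, label=1)
    return [
        mk("CASSLAPGATNEKLF", "CASSIRSSYEQYF", "GILGFVFTL"),
        mk("CAVSDLEPNSSASKI", "CASSYSTGDEQYF", "GILGFVFTL"),
        mk("CILRDGRGGADGLTF", "CASSPGQGSTEAFF", "NLVPMVATV"),
        mk("CAGAGSQGNLIF", "CSARDRTGNGYTF", "NLVPMVATV"),
        mk("CAVRDSNYQLIW", "CASSLGTGVEAFF", "ELAGIGILTV"),
    ]
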