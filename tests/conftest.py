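import numpy as np
import pytest

from drgcast.cohort import build_cohort, split_train_test
from drgcast.model import ModelConfig, train
from drgcast.synthgen import GenConfig, make_drg_catalog, simulate_cohort
from drgcast.textprep import assemble_document, build_vocab, clean_and_tokenize, encode_stay

SMALL_MAX_LEN = 250


@pytest.fixture(scope="session")
def gen_config():
    """Small cohort with strong, fast-accruing planted signal."""
    return GenConfig(seed=7, n_patients=300, n_drg_groups=5,
                     signal_rate_slope=0.004, note_len_mean=15,
                     background_vocab_size=300)


@pytest.fixture(scope="session")
def catalog(gen_config):
    return make_drg_catalog(gen_config)


@pytest.fixture(scope="session")
def stays(catalog, gen_config):
    return simulate_cohort(catalog, gen_config)


@pytest.fixture(scope="session")
def cohort(stays, catalog):
    return build_cohort(stays, catalog)


@pytest.fixture(scope="session")
def split(cohort):
    return split_train_test(cohort, 0.10, seed=3)


@pytest.fixture(scope="session")
def train_test(cohort, split):
    tr = [s for s in cohort.stays if s.patient_id not in split.test_patient_ids]
    te = [s for s in cohort.stays if s.patient_id in split.test_patient_ids]
    return tr, te


@pytest.fixture(scope="session")
def vocab(train_test):
    tr, _ = train_test
    return build_vocab(clean_and_tokenize(assemble_document(s, 48)) for s in tr)


@pytest.fixture(scope="session")
def trained_model(train_test, cohort, vocab):
    """A small classifier trained to convergence on the planted-signal cohort."""
    tr, _ = train_test
    docs = [encode_stay(s, 48, vocab, SMALL_MAX_LEN) for s in tr]
    cfg = ModelConfig(seed=5, embed_dim=24, n_filters=16, epochs=10, dropout=0.2)
    return train(docs, [s.drg_code for s in tr], cfg,
                 label_space=cohort.label_space, vocab=vocab)


@pytest.fixture(scope="session")
def test_docs(train_test, vocab):
    _, te = train_test
    return [encode_stay(s, 48, vocab, SMALL_MAX_LEN) for s in te]
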