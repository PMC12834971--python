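import numpy as np
import pytest

from bidirmol.codecs import Scheme, build_vocabulary, tokenize
from bidirmol.fixtures import (FixtureSpec, make_toy_corpus,
                               seed_fragment_tokens)
from bidirmol.mle_training import TrainingConfig, train

TOY_WINDOW = 30


@pytest.fixture(scope="session")
def toy_corpus():
    return make_toy_corpus(FixtureSpec(n_molecules=300, seed=11))


@pytest.fixture(scope="session")
def toy_tokens(toy_corpus):
    return [tokenize(r.raw, Scheme.SELFIES) for r in toy_corpus]


@pytest.fixture(scope="session")
def selfies_vocab(toy_tokens):
    return build_vocabulary(
        toy_tokens, Scheme.SELFIES,
        extra_tokens=seed_fragment_tokens(Scheme.SELFIES))


@pytest.fixture(scope="session")
def smiles_vocab(toy_corpus):
    token_lists = [tokenize(r.canonical_smiles, Scheme.SMILES)
                   for r in toy_corpus]
    return build_vocabulary(
        token_lists, Scheme.SMILES,
        extra_tokens=seed_fragment_tokens(Scheme.SMILES))


@pytest.fixture(scope="session")
def trained_models(toy_tokens, selfies_vocab):
    """Briefly trained SELFIES models of every variant (toy scale)."""
    cfg = TrainingConfig(epochs=2, folds=2, batch_size=32,
                         learning_rate=3e-3, m_total=TOY_WINDOW,
                         hidden_size=48, seed=3)
    out = {}
    for variant in ("forward", "backward", "fbrnn", "bimodal"):
        models, _, _ = train(toy_tokens, selfies_vocab, variant, cfg)
        out[variant] = models[0]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
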