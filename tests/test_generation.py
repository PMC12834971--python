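"""Generation schemes: stubs, positional laws, seed preservation."""

import numpy as np
import pytest
from rdkit import Chem

from bidirmol.codecs import Scheme, build_vocabulary, canonical_smiles
from bidirmol.fixtures import bundled_seeds, get_seed
from bidirmol.generation import (GenerationResult, SeedConstraint,
                                 generate, generate_backward,
                                 generate_bimodal, generate_fbrnn,
                                 generate_forward, sample_filtered,
                                 selfies_seed_intact, validate_seed)
from bidirmol.models import ModelConfig, build_model

from conftest import TOY_WINDOW


def _stub_pad_model(variant, vocab, bias_token=None, hidden=6):
    """A model that deterministically emits the pad token (or
    ``bias_token``) by a huge output bias."""
    m = build_model(ModelConfig(variant, len(vocab), hidden, 0))
    m.out.W.data[:] = 0.0
    m.out.b.data[:] = 0.0
    tok = vocab.pad_id if bias_token is None else vocab.index_of[bias_token]
    m.out.b.data[tok] += 60.0
    if variant == "fbrnn":
        m.out.b.data[len(vocab) + tok] += 60.0
    return m


@pytest.fixture(scope="module")
def small_vocab():
    return build_vocabulary([["[C]"], ["[N]"], ["[O]"], ["[Ring1]"],
                             ["[=Branch1]"], ["[Branch1]"], ["[=C]"],
                             ["[=N]"]], Scheme.SELFIES)


PYRIDINE = "[C][=C][C][=N][C][=C][Ring1][=Branch1]"


class TestStubModels:
    @pytest.mark.parametrize("fn,variant", [
        (generate_forward, "forward"),
        (generate_backward, "backward"),
        (generate_fbrnn, "fbrnn"),
        (generate_bimodal, "bimodal"),
    ])
    def test_pad_stub_returns_seed_exactly(self, small_vocab, fn, variant):
        seed = SeedConstraint(raw=PYRIDINE, scheme=Scheme.SELFIES)
        m = _stub_pad_model(variant, small_vocab)
        res = fn(m, small_vocab, seed=seed, m_total=14,
                 rng=np.random.default_rng(0), n=3)
        for r in res:
            assert r.core == PYRIDINE
            assert r.valid

    def test_pad_stub_unconstrained_empty_core(self, small_vocab):
        m = _stub_pad_model("forward", small_vocab)
        (r,) = generate_forward(m, small_vocab, m_total=8,
                                rng=np.random.default_rng(0), n=1)
        assert r.core == ""
        assert not r.valid

    def test_fbrnn_grows_two_tokens_per_iteration(self, small_vocab):
        m = _stub_pad_model("fbrnn", small_vocab, bias_token="[C]")
        seed = SeedConstraint(raw="[N]", scheme=Scheme.SELFIES)
        (r,) = generate_fbrnn(m, small_vocab, seed=seed, m_total=9,
                              rng=np.random.default_rng(0), n=1)
        # never freezes, so the window fills completely: 1 + 2k tokens
        assert len(r.core_tokens) == 9
        assert r.core_tokens[4] == "[N]"

    def test_bimodal_grows_one_token_per_step(self, small_vocab):
        m = _stub_pad_model("bimodal", small_vocab, bias_token="[C]")
        seed = SeedConstraint(raw="[N]", scheme=Scheme.SELFIES)
        (r,) = generate_bimodal(m, small_vocab, seed=seed, m_total=7,
                                rng=np.random.default_rng(0), n=1)
        assert len(r.core_tokens) == 7


class TestDeterminism:
    @pytest.mark.parametrize("variant",
                             ["forward", "backward", "fbrnn", "bimodal"])
    def test_fixed_rng_reproduces_output(self, trained_models, selfies_vocab,
                                         variant):
        seed = get_seed("amide").constraint(Scheme.SELFIES)
        a = generate(trained_models[variant], selfies_vocab, seed=seed,
                     m_total=TOY_WINDOW, rng=np.random.default_rng(77), n=8)
        b = generate(trained_models[variant], selfies_vocab, seed=seed,
                     m_total=TOY_WINDOW, rng=np.random.default_rng(77), n=8)
        assert [r.core for r in a] == [r.core for r in b]
        assert [r.seed_offset for r in a] == [r.seed_offset for r in b]


class TestPositionalLaws:
    def test_forward_seed_is_prefix(self, trained_models, selfies_vocab):
        seed = get_seed("pyridine").constraint(Scheme.SELFIES)
        res = generate_forward(trained_models["forward"], selfies_vocab,
                               seed=seed, m_total=TOY_WINDOW,
                               rng=np.random.default_rng(3), n=100)
        ok = [r for r in res if r.valid]
        assert ok
        for r in ok:
            assert r.seed_offset == 0
            assert "".join(r.core_tokens[:8]) == PYRIDINE

    def test_backward_seed_is_suffix(self, trained_models, selfies_vocab):
        seed = get_seed("pyridine").constraint(Scheme.SELFIES)
        res = generate_backward(trained_models["backward"], selfies_vocab,
                                seed=seed, m_total=TOY_WINDOW,
                                rng=np.random.default_rng(3), n=100)
        ok = [r for r in res if r.valid]
        assert ok
        for r in ok:
            assert r.seed_offset == len(r.core_tokens) - 8
            assert "".join(r.core_tokens[-8:]) == PYRIDINE

    @pytest.mark.parametrize("variant", ["fbrnn", "bimodal"])
    def test_bidirectional_offsets_cover_interior(self, trained_models,
                                                  selfies_vocab, variant):
        seed = get_seed("pyridine").constraint(Scheme.SELFIES,
                                               placement="random")
        res = generate(trained_models[variant], selfies_vocab, seed=seed,
                       m_total=TOY_WINDOW, rng=np.random.default_rng(5),
                       n=400)
        offsets = {r.seed_offset for r in res if r.valid}
        legal = TOY_WINDOW - 8 + 1
        assert len(offsets) > legal / 4  # strict > half is the batch check
        assert any(o > 0 for o in offsets)


class TestSeedPreservation:
    @pytest.mark.parametrize("variant", ["fbrnn", "bimodal"])
    def test_valid_results_contain_seed_substructure(self, trained_models,
                                                     selfies_vocab, variant):
        for frag in ("amide", "piperazine"):
            seed = get_seed(frag).constraint(Scheme.SELFIES)
            query = Chem.MolFromSmiles(get_seed(frag).smiles)
            res = generate(trained_models[variant], selfies_vocab, seed=seed,
                           m_total=TOY_WINDOW,
                           rng=np.random.default_rng(11), n=150)
            ok = [r for r in res if r.valid]
            assert ok
            for r in ok:
                smi = canonical_smiles(r.core, Scheme.SELFIES)
                assert Chem.MolFromSmiles(smi).HasSubstructMatch(query)

    def test_intactness_flags_clobbered_seed(self):
        seed_toks = ["[C]", "[C]", "[N]"]
        # a Branch1 just left of the seed consumes the seed's first token
        # as its index symbol (requires an atom before it to act on)
        assert not selfies_seed_intact(
            ["[C]", "[Branch1]"] + seed_toks, seed_toks, 2)
        assert selfies_seed_intact(["[C]"] + seed_toks, seed_toks, 1)

    def test_intactness_flags_ring_bridge(self):
        # suffix ring token closing back through the seed fuses it into a
        # new ring system
        seed_toks = ["[C]", "[C]", "[N]"]
        bridged = seed_toks + ["[C]", "[Ring1]", "[Ring1]"]
        assert not selfies_seed_intact(bridged, seed_toks, 0)


class TestValidateSeed:
    def test_bundled_seeds_all_pass(self):
        for frag in bundled_seeds():
            for scheme in (Scheme.SMILES, Scheme.SELFIES):
                diag = validate_seed(frag.constraint(scheme))
                assert diag.ok, (frag.name, diag.reasons)

    def test_closed_valence_terminal_rejected(self):
        # indole mis-encoded so the final nitrogen holds three bonds
        seed = SeedConstraint(raw="C1=CC=C2C(=C1)CC=N2",
                              scheme=Scheme.SMILES)
        diag = validate_seed(seed)
        assert not diag.ok
        assert not diag.open_valence

    def test_periodic_token_list_flagged(self):
        seed = SeedConstraint(raw="[C][C]", scheme=Scheme.SELFIES)
        diag = validate_seed(seed)
        assert not diag.aperiodic
        assert not diag.ok


class TestSampleFiltered:
    def test_deterministic_stub_caps_at_one_unique(self, small_vocab):
        m = _stub_pad_model("forward", small_vocab, bias_token="[C]")
        res, info = sample_filtered(m, small_vocab, 5, m_total=6,
                                    rng=np.random.default_rng(0),
                                    attempt_factor=4)
        assert len(res) == 1
        assert info["capped"]

    def test_novelty_filter_removes_training_structures(self, trained_models,
                                                        selfies_vocab):
        rng = np.random.default_rng(9)
        m = trained_models["fbrnn"]
        first, _ = sample_filtered(m, selfies_vocab, 10, m_total=TOY_WINDOW,
                                   rng=rng)
        planted = {canonical_smiles(r.core, Scheme.SELFIES) for r in first}
        res, _ = sample_filtered(m, selfies_vocab, 10, m_total=TOY_WINDOW,
                                 training_set=planted,
                                 rng=np.random.default_rng(9))
        for r in res:
            assert canonical_smiles(r.core, Scheme.SELFIES) not in planted
            assert r.novel

    def test_selfies_sampling_all_valid(self, trained_models, selfies_vocab):
        res, info = sample_filtered(trained_models["fbrnn"], selfies_vocab,
                                    50, m_total=TOY_WINDOW,
                                    rng=np.random.default_rng(21))
        assert len(res) == 50
        assert all(r.valid for r in res)


class TestSmilesScheme:
    def test_constrained_smiles_validity_uses_substructure(self,
                                                           smiles_vocab):
        seed = get_seed("amide").constraint(Scheme.SMILES)
        m = _stub_pad_model("forward", smiles_vocab)
        res = generate_forward(m, smiles_vocab, seed=seed, m_total=10,
                               rng=np.random.default_rng(0), n=2)
        query = Chem.MolFromSmiles("CC(=O)N")
        for r in res:
            assert r.core == "CC(=O)N"
            assert r.valid
            assert Chem.MolFromSmiles(r.core).HasSubstructMatch(query)

    def test_invalid_smiles_marked(self, smiles_vocab):
        m = _stub_pad_model("forward", smiles_vocab, bias_token="1")
        (r,) = generate_forward(m, smiles_vocab, m_total=6,
                                rng=np.random.default_rng(0), n=1)
        assert not r.valid
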