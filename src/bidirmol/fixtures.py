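"""Synthetic corpora and the bundled seed fragments.

Real training corpora for these models are hundreds of thousands of
drug-like molecules; the fixture generator stands in with corpora of
small random molecules built by sampling SELFIES token strings over a
restricted alphabet (valid by construction), decoding them, and keeping
the distinct structures.  Corpus strings are the canonical SMILES and
their re-encoded SELFIES, so both schemes train on the same molecules.

The six bundled seed fragments are common bioactive substructure
constraints (indole, pyridine, benzimidazole, piperazine, the amide
group, quinoline), stored as SMILES with matching SELFIES encodings and
chosen so both terminal attachment atoms keep an open valence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .codecs import MoleculeRecord, Scheme
from .generation import SeedConstraint, validate_seed
from .selfies_codec import SelfiesError, decode_selfies, encode_selfies

import numpy as np

__all__ = [
    "SeedFragment",
    "SEED_FRAGMENTS",
    "bundled_seeds",
    "get_seed",
    "seed_fragment_tokens",
    "FixtureSpec",
    "make_toy_corpus",
    "corpus_strings",
    "TOY_ALPHABET",
]


@dataclass(frozen=True)
class SeedFragment:
    name: str
    smiles: str
    selfies: str

    def constraint(self, scheme: Scheme, placement: str = "fixed"
                   ) -> SeedConstraint:
        raw = self.smiles if Scheme(scheme) is Scheme.SMILES else self.selfies
        return SeedConstraint(raw=raw, scheme=scheme, placement=placement)


SEED_FRAGMENTS = (
    SeedFragment(
        "indole", "C1=CC=C2C(=C1)C=CN2",
        "[C][=C][C][=C][C][=Branch1][Ring2][=C][Ring1][=Branch1]"
        "[C][=C][N][Ring1][=Branch1]"),
    SeedFragment(
        "pyridine", "C1=CC=NC=C1",
        "[C][=C][C][=N][C][=C][Ring1][=Branch1]"),
    SeedFragment(
        "benzimidazole", "C1=CC=C2C(=C1)N=CN2",
        "[C][=C][C][=C][C][=Branch1][Ring2][=C][Ring1][=Branch1]"
        "[N][=C][N][Ring1][=Branch1]"),
    SeedFragment(
        "piperazine", "C1CNCCN1",
        "[C][C][N][C][C][N][Ring1][=Branch1]"),
    SeedFragment(
        "amide", "CC(=O)N",
        "[C][C][=Branch1][C][=O][N]"),
    SeedFragment(
        "quinoline", "C1=CC=C2C=CC=NC2=C1",
        "[C][=C][C][=C][C][=C][C][=N][C][Ring1][=Branch1]"
        "[=C][Ring1][#Branch2]"),
)


def bundled_seeds() -> tuple[SeedFragment, ...]:
    """The six bundled constraint fragments (all pass validate_seed)."""
    return SEED_FRAGMENTS


def get_seed(name: str) -> SeedFragment:
    for frag in SEED_FRAGMENTS:
        if frag.name == name.lower():
            return frag
    raise KeyError(f"no bundled seed named {name!r}")


def seed_fragment_tokens(scheme: Scheme) -> tuple[str, ...]:
    """Union of the bundled seeds' tokens (pass to build_vocabulary so a
    corpus-derived vocabulary can express every constraint)."""
    from .codecs import tokenize

    out: set[str] = set()
    for frag in SEED_FRAGMENTS:
        raw = frag.smiles if Scheme(scheme) is Scheme.SMILES else frag.selfies
        out |= set(tokenize(raw, scheme))
    return tuple(sorted(out))


#: Restricted SELFIES alphabet keeping decoded fixtures small and
#: QED/SA-computable quickly.
TOY_ALPHABET = (
    "[C]", "[=C]", "[N]", "[=N]", "[O]", "[=O]",
    "[Branch1]", "[=Branch1]", "[Ring1]",
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 500
    min_tokens: int = 4
    max_tokens: int = 12
    alphabet: tuple = TOY_ALPHABET
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1 or self.max_tokens < 2 \
                or self.min_tokens < 1 or self.min_tokens > self.max_tokens:
            raise ValueError("bad fixture spec")


def make_toy_corpus(spec: FixtureSpec = FixtureSpec()) -> list[MoleculeRecord]:
    """Distinct random small molecules, deterministic under the seed.

    Each record's ``raw`` is the SELFIES encoding of the canonical
    structure; ``canonical_smiles`` carries the SMILES form.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    cap = 1000 * spec.n_molecules
    while len(records) < spec.n_molecules and attempts < cap:
        attempts += 1
        length = int(rng.integers(spec.min_tokens, spec.max_tokens + 1))
        toks = [spec.alphabet[i] for i in
                rng.integers(0, len(spec.alphabet), size=length)]
        smiles = decode_selfies(toks)
        if smiles is None or smiles in seen:
            continue
        try:
            selfies = encode_selfies(smiles)
        except SelfiesError:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord(
            raw=selfies, scheme=Scheme.SELFIES,
            canonical_smiles=smiles, valid=True))
    if len(records) < spec.n_molecules:
        raise RuntimeError("could not assemble the requested corpus size")
    return records


def corpus_strings(records: list[MoleculeRecord], scheme: Scheme) -> list[str]:
    """The corpus in one scheme (canonical SMILES or re-encoded SELFIES)."""
    if Scheme(scheme) is Scheme.SMILES:
        return [r.canonical_smiles for r in records]
    return [r.raw for r in records]
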