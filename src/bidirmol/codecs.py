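"""Tokenisation, vocabularies and fixed-length training windows.

Molecular strings come in two schemes: SMILES (tokenised by a standard
ordered regex over bracket atoms, two-letter halogens, single atoms, bond /
branch / ring symbols) and SELFIES (bracketed units).  Training and
generation operate on fixed-length *windows*: the raw token sequence plus a
single start token (``G`` / ``[G]``), padded on both sides with a pad token
(``A`` / ``[A]``) to a common length.  Pads are restricted to a contiguous
prefix and suffix so that stripping the specials is an exact inverse of the
window construction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import selfies_codec
from .selfies_codec import SelfiesError, tokenize_selfies

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Scheme",
    "TokenVocabulary",
    "EncodedString",
    "MoleculeRecord",
    "tokenize_smiles",
    "tokenize_selfies",
    "tokenize",
    "build_vocabulary",
    "encode_window",
    "strip_special",
    "convert_encoding",
    "is_valid",
    "canonical_smiles",
    "read_smi",
    "write_smi",
]


class Scheme(str, Enum):
    SMILES = "smiles"
    SELFIES = "selfies"


START_TOKEN = {Scheme.SMILES: "G", Scheme.SELFIES: "[G]"}
PAD_TOKEN = {Scheme.SMILES: "A", Scheme.SELFIES: "[A]"}

# ordered alternation: bracket atoms, %nn ring closures, two-letter organic
# atoms, single atoms (incl. aromatic), bonds, branches, ring digits
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\[\]]+\]|%\d{2}|Cl|Br|[BCNOPSFI]|[bcnops]|[-=#$:/\\.()]|\d)"
)


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into atomic tokens (lossless)."""
    if not s:
        raise ValueError("empty SMILES string")
    tokens = _SMILES_TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise ValueError(f"cannot tokenize SMILES: {s!r}")
    return tokens


def tokenize(s: str, scheme: Scheme) -> list[str]:
    if Scheme(scheme) is Scheme.SMILES:
        return tokenize_smiles(s)
    return tokenize_selfies(s)


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token set with start/pad specials (pad is index 0)."""

    scheme: Scheme
    tokens: tuple[str, ...]
    start_token: str
    pad_token: str
    index_of: dict[str, int] = field(compare=False, repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "index_of", {t: i for i, t in enumerate(self.tokens)}
        )
        if len(self.index_of) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (self.start_token, self.pad_token):
            if special not in self.index_of:
                raise ValueError(f"special token {special!r} missing")
        if self.start_token == self.pad_token:
            raise ValueError("start and pad tokens must differ")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index_of[self.pad_token]

    @property
    def start_id(self) -> int:
        return self.index_of[self.start_token]

    def encode(self, tokens: list[str]) -> list[int]:
        try:
            return [self.index_of[t] for t in tokens]
        except KeyError as e:
            raise KeyError(f"token {e.args[0]!r} not in vocabulary") from None

    def decode(self, ids) -> list[str]:
        return [self.tokens[int(i)] for i in ids]

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": Scheme(self.scheme).value,
                "tokens": list(self.tokens),
                "start_token": self.start_token,
                "pad_token": self.pad_token,
            },
            indent=None,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "TokenVocabulary":
        d = json.loads(s)
        return cls(
            scheme=Scheme(d["scheme"]),
            tokens=tuple(d["tokens"]),
            start_token=d["start_token"],
            pad_token=d["pad_token"],
        )


def build_vocabulary(corpus: list[list[str]], scheme: Scheme,
                     extra_tokens: tuple[str, ...] = ()) -> TokenVocabulary:
    """Vocabulary = pad, start, then sorted distinct corpus tokens.

    ``extra_tokens`` admits tokens beyond the corpus (e.g. those of seed
    fragments intended for constrained generation).
    """
    if not corpus:
        raise ValueError("empty corpus")
    scheme = Scheme(scheme)
    start, pad = START_TOKEN[scheme], PAD_TOKEN[scheme]
    distinct = sorted(
        ({t for toks in corpus for t in toks} | set(extra_tokens))
        - {start, pad})
    return TokenVocabulary(
        scheme=scheme,
        tokens=(pad, start) + tuple(distinct),
        start_token=start,
        pad_token=pad,
    )


@dataclass
class EncodedString:
    """A fixed-length token-id window holding one start token."""

    token_ids: np.ndarray
    start_offset: int
    scheme: Scheme

    def __post_init__(self):
        self.token_ids = np.asarray(self.token_ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.token_ids)


def _insert_position(n_tokens: int, placement, rng) -> int:
    """0-based insert position of the start token within the core."""
    if placement == "fixed":
        return (n_tokens + 1) // 2
    if placement == "random":
        if rng is None:
            raise ValueError("random placement requires an rng")
        return int(rng.integers(0, n_tokens + 1))
    if placement == "left":
        return 0
    if placement == "right":
        return n_tokens
    raise ValueError(f"unknown placement {placement!r}")


def encode_window(
    tokens: list[str],
    vocab: TokenVocabulary,
    m_total: int,
    placement: str = "fixed",
    rng: np.random.Generator | None = None,
) -> EncodedString:
    """Insert the start token, then pad both sides to length ``m_total``.

    ``placement`` is ``fixed`` (middle of the core), ``random`` (uniform
    legal position), ``left`` or ``right`` (ends of the core, the layouts
    used by purely forward / backward models).
    """
    n = len(tokens)
    if n + 1 > m_total:
        raise ValueError(f"core of {n + 1} tokens exceeds window {m_total}")
    g = _insert_position(n, placement, rng)
    core = list(tokens[:g]) + [vocab.start_token] + list(tokens[g:])
    n_pad = m_total - len(core)
    left = n_pad // 2
    window = (
        [vocab.pad_token] * left + core + [vocab.pad_token] * (n_pad - left)
    )
    return EncodedString(
        token_ids=np.array(vocab.encode(window), dtype=np.int64),
        start_offset=left + g,
        scheme=vocab.scheme,
    )


def strip_special(window: EncodedString, vocab: TokenVocabulary) -> str:
    """Remove start/pad tokens and concatenate the remaining core."""
    toks = vocab.decode(window.token_ids)
    return "".join(
        t for t in toks if t != vocab.start_token and t != vocab.pad_token
    )


def core_tokens(window: EncodedString, vocab: TokenVocabulary) -> list[str]:
    toks = vocab.decode(window.token_ids)
    return [t for t in toks if t != vocab.start_token and t != vocab.pad_token]


def canonical_smiles(s: str, scheme: Scheme) -> str | None:
    """Canonical SMILES of a string in either scheme, or None if invalid."""
    if Scheme(scheme) is Scheme.SMILES:
        mol = Chem.MolFromSmiles(s)
        if mol is None or mol.GetNumAtoms() == 0:
            return None
        return Chem.MolToSmiles(mol)
    try:
        return selfies_codec.decode_selfies(s)
    except SelfiesError:
        return None


def convert_encoding(s: str, from_scheme: Scheme, to_scheme: Scheme) -> str:
    """Translate between SMILES and SELFIES (canonical round trips)."""
    from_scheme, to_scheme = Scheme(from_scheme), Scheme(to_scheme)
    if from_scheme is to_scheme:
        return s
    if from_scheme is Scheme.SMILES:
        return selfies_codec.encode_selfies(s)
    smiles = selfies_codec.decode_selfies(s)
    if smiles is None:
        raise SelfiesError(f"SELFIES string decodes to no atoms: {s!r}")
    return smiles


def is_valid(s: str, scheme: Scheme) -> bool:
    """Syntactic validity: parses to a non-empty molecule."""
    if not s:
        return False
    return canonical_smiles(s, scheme) is not None


@dataclass
class MoleculeRecord:
    raw: str
    scheme: Scheme
    canonical_smiles: str | None = None
    valid: bool = False

    @classmethod
    def from_string(cls, raw: str, scheme: Scheme) -> "MoleculeRecord":
        can = canonical_smiles(raw, scheme)
        return cls(raw=raw, scheme=Scheme(scheme),
                   canonical_smiles=can, valid=can is not None)


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one string per line, optional name, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            out.append((parts[0], parts[1] if len(parts) > 1 else ""))
    return out


def write_smi(path, strings, names=None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(strings):
            name = names[i] if names is not None else ""
            fh.write(f"{s} {name}".rstrip() + "\n")
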