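"""Seed-constrained and unconstrained string generation.

Every scheme fills a fixed-length window outward from its starting
material (the lone start token, or a seed fragment replacing it) and
strips the specials afterwards:

* ``forward``  — seed at the left end of the core, tokens appended to the
  right by sampling the temperature softmax;
* ``backward`` — mirror image, tokens prepended on the left;
* ``fbrnn``    — two tokens per iteration, one per side, grown
  symmetrically around the seed centre;
* ``bimodal``  — one token per step, alternating sides (step 1 is
  forward), the whole current window re-read before each emission.

There is no end-of-string token: a side that samples the pad token is
frozen (all its further emissions forced to pad), so pads always form a
contiguous prefix and suffix and post-processing is exact trimming.

A constrained result is *valid* only if the seed survived decoding
intact: for SMILES this is an RDKit substructure match against the seed;
for SELFIES the decoder's token-level provenance must show every seed
token consumed in its original role with its original bonds (the analogue
of discarding strings whose seed was clobbered by a valence-rule
violation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import selfies_codec
from .chem_space import check_aperiodicity
from .codecs import (EncodedString, Scheme, TokenVocabulary, canonical_smiles,
                     tokenize)
from .models import (BimodalModel, FBRNNModel, UnidirectionalModel,
                     temperature_softmax)
from .nn import no_grad
from .selfies_codec import decode_graph

__all__ = [
    "SeedConstraint",
    "GenerationResult",
    "SeedDiagnostics",
    "validate_seed",
    "generate_forward",
    "generate_backward",
    "generate_fbrnn",
    "generate_bimodal",
    "generate",
    "sample_filtered",
    "selfies_seed_intact",
]


@dataclass
class SeedConstraint:
    """A substring that must appear intact in every generated string."""

    raw: str
    scheme: Scheme
    tokens: list[str] = field(default=None)
    placement: str = "fixed"
    aperiodic: bool = field(default=None)

    def __post_init__(self):
        self.scheme = Scheme(self.scheme)
        if self.tokens is None:
            self.tokens = tokenize(self.raw, self.scheme)
        if not self.tokens:
            raise ValueError("empty seed")
        if self.aperiodic is None:
            self.aperiodic = check_aperiodicity(self.tokens)


@dataclass
class GenerationResult:
    full_window: EncodedString
    core: str
    valid: bool
    seed_offset: int
    scheme: Scheme
    novel: bool | None = None
    core_tokens: list[str] = field(default_factory=list, repr=False)


@dataclass
class SeedDiagnostics:
    ok: bool
    reasons: list[str]
    decodable: bool
    open_valence: bool
    aperiodic: bool


def validate_seed(seed: SeedConstraint) -> SeedDiagnostics:
    """Check decodability, open valence at both attachment atoms, and
    aperiodicity of the token list."""
    reasons = []
    smiles = canonical_smiles(seed.raw, seed.scheme)
    decodable = smiles is not None
    if not decodable:
        reasons.append("seed does not decode to a molecule")
    open_valence = False
    if decodable:
        if seed.scheme is Scheme.SMILES:
            mol = Chem.MolFromSmiles(seed.raw)
            first, last = 0, mol.GetNumAtoms() - 1
        else:
            g = decode_graph(seed.tokens)
            mol = selfies_codec.decode_to_mol(seed.tokens)
            first, last = 0, g.n_atoms - 1
        h_first = mol.GetAtomWithIdx(first).GetTotalNumHs()
        h_last = mol.GetAtomWithIdx(last).GetTotalNumHs()
        open_valence = h_first >= 1 and h_last >= 1
        if not open_valence:
            reasons.append(
                "terminal attachment atom has no open valence "
                f"(H counts: first={h_first}, last={h_last})")
    if not seed.aperiodic:
        reasons.append("seed token list is a whole number of repeats")
    return SeedDiagnostics(
        ok=decodable and open_valence and seed.aperiodic,
        reasons=reasons,
        decodable=decodable,
        open_valence=open_valence,
        aperiodic=seed.aperiodic,
    )


# ---------------------------------------------------------------------------
# window machinery
# ---------------------------------------------------------------------------


def _initial_window(vocab: TokenVocabulary, seed: SeedConstraint | None,
                    m_total: int, batch: int, placement: str,
                    rng: np.random.Generator):
    """Pad-filled (batch, M) windows holding the starting material.

    Returns (ids, spans) where spans[b] = (l0, r0), the inclusive span of
    the seed (or the start token) in row b.
    """
    core = vocab.encode(seed.tokens) if seed is not None \
        else [vocab.start_id]
    n = len(core)
    if n >= m_total:
        raise ValueError(f"seed of {n} tokens does not fit window {m_total}"
                         " with room to grow")
    ids = np.full((batch, m_total), vocab.pad_id, dtype=np.int64)
    spans = np.empty((batch, 2), dtype=np.int64)
    for b in range(batch):
        if placement == "fixed":
            l0 = (m_total - n) // 2
        elif placement == "random":
            l0 = int(rng.integers(0, m_total - n + 1))
        elif placement == "left":
            l0 = 0
        elif placement == "right":
            l0 = m_total - n
        else:
            raise ValueError(f"unknown placement {placement!r}")
        ids[b, l0:l0 + n] = core
        spans[b] = (l0, l0 + n - 1)
    return ids, spans


def _finish(ids: np.ndarray, spans: np.ndarray, vocab: TokenVocabulary,
            seed: SeedConstraint | None, scheme: Scheme
            ) -> list[GenerationResult]:
    out = []
    n_seed = len(seed.tokens) if seed is not None else 0
    for b in range(ids.shape[0]):
        row = ids[b]
        non_pad = np.flatnonzero(row != vocab.pad_id)
        toks = [vocab.tokens[i] for i in row[non_pad]
                if i != vocab.start_id]
        core = "".join(toks)
        first = int(non_pad[0]) if non_pad.size else 0
        offset = int(spans[b, 0]) - first if seed is not None else 0
        valid = _result_valid(core, toks, scheme, seed, offset)
        out.append(GenerationResult(
            full_window=EncodedString(row.copy(), int(spans[b, 0]), scheme),
            core=core, core_tokens=toks, valid=valid,
            seed_offset=offset, scheme=scheme))
    return out


def selfies_seed_intact(core_tokens: list[str], seed_tokens: list[str],
                        offset: int) -> bool:
    """True iff the seed token run decoded to its isolated structure.

    Compares the decoder provenance of the full core against an isolated
    decode of the seed: same token roles, same atoms, and exactly the same
    bonds *between* seed atoms.  Bonds attaching outside material to seed
    atoms are allowed (those are the attachment points) unless they close
    a new ring through the seed — a bridge fusing the seed into a larger
    ring system changes the seed's perceived aromaticity, so such results
    are discarded like any other valence-rule clobbering.
    """
    full = decode_graph(core_tokens)
    iso = decode_graph(seed_tokens)
    n = len(seed_tokens)
    if full.roles[offset:offset + n] != iso.roles:
        return False
    in_seed_f = {src: i for i, src in enumerate(full.atom_source)
                 if offset <= src < offset + n}
    in_seed_i = {src: i for i, src in enumerate(iso.atom_source)}
    if {s - offset for s in in_seed_f} != set(in_seed_i):
        return False
    atom_of = {}  # isolated atom index -> full atom index
    for src, ia in in_seed_i.items():
        fa = in_seed_f[src + offset]
        if full.elements[fa] != iso.elements[ia]:
            return False
        atom_of[ia] = fa
    seed_atoms = set(atom_of.values())
    internal_full = {
        (min(a, b), max(a, b)): o
        for a, b, o, _src in full.bonds
        if a in seed_atoms and b in seed_atoms
    }
    internal_iso = {
        (min(atom_of[a], atom_of[b]), max(atom_of[a], atom_of[b])): o
        for a, b, o, _src in iso.bonds
    }
    if internal_full != internal_iso:
        return False
    # no new cycle may pass through the seed: every attachment bond
    # (one endpoint in the seed) must be a bridge in the full molecule
    mol = selfies_codec._graph_to_mol(full)
    if mol is None:
        return False
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (a in seed_atoms) != (b in seed_atoms) and bond.IsInRing():
            return False
    return True


def _result_valid(core: str, toks: list[str], scheme: Scheme,
                  seed: SeedConstraint | None, offset: int) -> bool:
    if scheme is Scheme.SMILES:
        mol = Chem.MolFromSmiles(core) if core else None
        if mol is None or mol.GetNumAtoms() == 0:
            return False
        if seed is not None:
            query = Chem.MolFromSmiles(seed.raw)
            return mol.HasSubstructMatch(query)
        return True
    # SELFIES
    if not toks:
        return False
    if seed is not None and not selfies_seed_intact(toks, seed.tokens, offset):
        return False
    return selfies_codec.decode_to_mol(toks) is not None


def _sample_ids(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical sampling, one draw per row."""
    cum = probs.cumsum(axis=-1)
    cum[:, -1] = 1.0 + 1e-12
    u = rng.random((probs.shape[0], 1))
    return (u > cum).sum(axis=-1).astype(np.int64)


# ---------------------------------------------------------------------------
# scheme-specific generators
# ---------------------------------------------------------------------------


def _generate_unidirectional(model: UnidirectionalModel,
                             vocab: TokenVocabulary,
                             seed: SeedConstraint | None, m_total: int,
                             temperature: float, rng: np.random.Generator,
                             n: int, reverse: bool) -> list[GenerationResult]:
    """Shared forward/backward machinery (backward = reversed problem)."""
    scheme = vocab.scheme
    rev_seed = seed
    if reverse and seed is not None:
        rev_seed = SeedConstraint(raw=seed.raw, scheme=seed.scheme,
                                  tokens=list(reversed(seed.tokens)))
    ids, spans = _initial_window(vocab, rev_seed, m_total, n, "left", rng)
    k = int(spans[0, 1]) + 1  # prefix length, same in every row
    model.set_train(False)
    with no_grad():
        state = model.zero_state(n)
        logits = None
        for pos in range(k):
            logits, state = model.step(ids[:, pos], state)
        frozen = np.zeros(n, dtype=bool)
        for pos in range(k, m_total):
            probs = temperature_softmax(logits, temperature)
            tok = _sample_ids(probs, rng)
            tok[frozen] = vocab.pad_id
            frozen |= tok == vocab.pad_id
            ids[:, pos] = tok
            logits, state = model.step(tok, state)
    if reverse:
        ids = ids[:, ::-1]
        spans = np.stack(
            [m_total - 1 - spans[:, 1], m_total - 1 - spans[:, 0]], axis=1)
    return _finish(ids, spans, vocab, seed, scheme)


def generate_forward(model, vocab, seed=None, m_total=40, temperature=1.0,
                     rng=None, n=1):
    rng = rng if rng is not None else np.random.default_rng()
    return _generate_unidirectional(model, vocab, seed, m_total, temperature,
                                    rng, n, reverse=False)


def generate_backward(model, vocab, seed=None, m_total=40, temperature=1.0,
                      rng=None, n=1):
    rng = rng if rng is not None else np.random.default_rng()
    return _generate_unidirectional(model, vocab, seed, m_total, temperature,
                                    rng, n, reverse=True)


def generate_fbrnn(model: FBRNNModel, vocab, seed=None, m_total=40,
                   temperature=1.0, rng=None, n=1, placement=None):
    rng = rng if rng is not None else np.random.default_rng()
    placement = placement or (seed.placement if seed is not None else "fixed")
    ids, spans = _initial_window(vocab, seed, m_total, n, placement, rng)
    model.set_train(False)
    rows = np.arange(n)
    with no_grad():
        state = model.zero_state(n)
        centres = (spans[:, 0] + spans[:, 1]) // 2
        frozen_l = np.zeros(n, dtype=bool)
        frozen_r = np.zeros(n, dtype=bool)
        t_max = int(max(centres.max(), (m_total - 1 - centres).max()))
        for t in range(t_max + 1):
            lpos, rpos = centres - t, centres + t
            left_read = np.where(
                lpos >= 0, ids[rows, np.clip(lpos, 0, m_total - 1)],
                vocab.pad_id)
            right_read = np.where(
                rpos <= m_total - 1,
                ids[rows, np.clip(rpos, 0, m_total - 1)], vocab.pad_id)
            y_minus, y_plus, state = model.step(left_read, right_read, state)
            # right emission at centres + t + 1
            tgt = centres + t + 1
            write = (tgt <= m_total - 1) & (tgt > spans[:, 1])
            if write.any():
                tok = _sample_ids(
                    temperature_softmax(y_plus, temperature), rng)
                tok[frozen_r] = vocab.pad_id
                frozen_r |= write & (tok == vocab.pad_id)
                ids[rows[write], tgt[write]] = tok[write]
            # left emission at centres - t - 1
            tgt = centres - t - 1
            write = (tgt >= 0) & (tgt < spans[:, 0])
            if write.any():
                tok = _sample_ids(
                    temperature_softmax(y_minus, temperature), rng)
                tok[frozen_l] = vocab.pad_id
                frozen_l |= write & (tok == vocab.pad_id)
                ids[rows[write], tgt[write]] = tok[write]
    return _finish(ids, spans, vocab, seed, vocab.scheme)


def generate_bimodal(model: BimodalModel, vocab, seed=None, m_total=40,
                     temperature=1.0, rng=None, n=1, placement=None):
    rng = rng if rng is not None else np.random.default_rng()
    placement = placement or (seed.placement if seed is not None else "fixed")
    ids, spans = _initial_window(vocab, seed, m_total, n, placement, rng)
    model.set_train(False)
    with no_grad():
        left = spans[:, 0].copy()
        right = spans[:, 1].copy()
        frozen_l = np.zeros(n, dtype=bool)
        frozen_r = np.zeros(n, dtype=bool)
        step = 1
        while True:
            can_r = (right + 1 <= m_total - 1) & ~frozen_r
            can_l = (left - 1 >= 0) & ~frozen_l
            if not (can_r.any() or can_l.any()):
                break  # remaining positions stay pad
            forward = step % 2 == 1
            step += 1
            sel_all = can_r if forward else can_l
            if not sel_all.any():
                continue
            pos_all = (right + 1) if forward else (left - 1)
            # rows share the emission position only under fixed placement;
            # group rows by position so each pass is one batched re-read
            for pos in np.unique(pos_all[sel_all]):
                sel = sel_all & (pos_all == pos)
                logits = model.next_token_logits(ids[sel], int(pos))
                tok = _sample_ids(
                    temperature_softmax(logits, temperature), rng)
                ids[sel, int(pos)] = tok
                if forward:
                    frozen_r[sel] |= tok == vocab.pad_id
                    right[sel] += 1
                else:
                    frozen_l[sel] |= tok == vocab.pad_id
                    left[sel] -= 1
    return _finish(ids, spans, vocab, seed, vocab.scheme)


_GENERATORS = {
    "forward": generate_forward,
    "backward": generate_backward,
    "fbrnn": generate_fbrnn,
    "bimodal": generate_bimodal,
}


def generate(model, vocab, seed=None, m_total=40, temperature=1.0,
             rng=None, n=1):
    """Dispatch on the model's configured variant."""
    return _GENERATORS[model.config.variant](
        model, vocab, seed=seed, m_total=m_total, temperature=temperature,
        rng=rng, n=n)


def sample_filtered(model, vocab, n_target: int, seed=None,
                    training_set: set[str] | None = None, m_total=40,
                    temperature=1.0, rng=None, attempt_factor: int = 50):
    """Draw until ``n_target`` unique, valid, novel results are collected.

    ``training_set`` is a set of canonical SMILES; novelty is judged at the
    canonical-structure level.  Returns (results, info) where info reports
    attempts made and whether the attempt cap was hit.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    cap = attempt_factor * n_target
    kept: list[GenerationResult] = []
    seen_raw: set[str] = set()
    attempts = 0
    while len(kept) < n_target and attempts < cap:
        batch = min(max(n_target - len(kept), 16), 256, cap - attempts)
        results = generate(model, vocab, seed=seed, m_total=m_total,
                           temperature=temperature, rng=rng, n=batch)
        attempts += batch
        for r in results:
            if r.core in seen_raw:
                continue
            seen_raw.add(r.core)
            if not r.valid:
                continue
            if training_set is not None:
                can = canonical_smiles(r.core, r.scheme)
                r.novel = can not in training_set
                if not r.novel:
                    continue
            kept.append(r)
            if len(kept) == n_target:
                break
    info = {"attempts": attempts, "capped": len(kept) < n_target}
    return kept, info
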