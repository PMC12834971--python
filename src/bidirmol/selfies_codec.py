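"""Robust SELFIES-style molecular string codec.

SELFIES (self-referencing embedded strings) is a formal-automaton encoding of
molecular graphs in which *every* sequence of alphabet tokens derives a valid
molecule: bond orders are capped by the remaining valence of the atoms
involved, and special tokens that cannot apply in the current derivation state
are skipped.  This module implements a self-contained subset of the v2
dialect covering neutral organic-subset molecules (B, C, N, O, P, S and the
halogens; no charges, isotopes or stereochemistry), which is sufficient for
the bundled seed fragments and the synthetic corpora used throughout the
package.

Grammar implemented
-------------------
* atom tokens ``[C]``, ``[=C]``, ``[#N]``, ... — the prefix requests the
  order of the bond to the current attachment atom; the realised order is
  ``min(prefix, free valence of both partners)``.
* ``[BranchL]`` / ``[=BranchL]`` / ``[#BranchL]`` — open a side chain.  The
  following *L* tokens are read as hexadecimal index symbols giving ``Q``;
  the branch body is the next ``Q + 1`` tokens.  A branch token is skipped
  when fewer than two units of valence remain on the attachment atom.
* ``[RingL]`` / ``[=RingL]`` — close a ring between the current atom and the
  atom derived ``Q + 1`` positions earlier.
* hexadecimal index alphabet (0-15)::

      [C] [Ring1] [Ring2] [Branch1] [=Branch1] [#Branch1] [Branch2]
      [=Branch2] [#Branch2] [O] [N] [=N] [=C] [#C] [S] [P]

  Any token outside this table counts as 0, as in the published dialect.

The decoder records, for every input token, the role it was consumed in
(``atom``, ``branch``, ``ring``, ``index``, ``skipped`` or ``unused``) and,
for every derived atom and bond, the index of the token that produced it.
This provenance is what the constrained-generation filter uses to decide
whether a seed substring survived decoding intact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem

__all__ = [
    "VALENCES",
    "INDEX_ALPHABET",
    "tokenize_selfies",
    "decode_graph",
    "decode_selfies",
    "decode_to_mol",
    "encode_selfies",
    "SelfiesError",
    "DecodedGraph",
]


class SelfiesError(ValueError):
    """Raised for strings outside the supported dialect."""


#: Default valence caps of the supported neutral elements.
VALENCES = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Hexadecimal index symbols, position = numeric value.
INDEX_ALPHABET = [
    "[C]", "[Ring1]", "[Ring2]", "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]", "[O]", "[N]", "[=N]", "[=C]",
    "[#C]", "[S]", "[P]",
]
_INDEX_OF = {t: i for i, t in enumerate(INDEX_ALPHABET)}

_BOND_PREFIX = {"": 1, "=": 2, "#": 3}
_PREFIX_OF_ORDER = {1: "", 2: "=", 3: "#"}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(r"\[([=#]?)([A-Z][a-z]?)\]")
_BRANCH_RE = re.compile(r"\[([=#]?)Branch([123])\]")
_RING_RE = re.compile(r"\[([=#]?)Ring([123])\]")


def tokenize_selfies(s: str) -> list[str]:
    """Split a SELFIES string into its bracketed tokens.

    Raises :class:`SelfiesError` on dangling brackets or stray characters
    between tokens.
    """
    if not isinstance(s, str) or not s:
        raise SelfiesError("empty SELFIES string")
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        raise SelfiesError(f"malformed SELFIES string: {s!r}")
    return tokens


def _classify(token: str):
    """Return ('atom'|'branch'|'ring', order, payload) or ('other', 0, None)."""
    m = _BRANCH_RE.fullmatch(token)
    if m:
        return "branch", _BOND_PREFIX[m.group(1)], int(m.group(2))
    m = _RING_RE.fullmatch(token)
    if m:
        return "ring", _BOND_PREFIX[m.group(1)], int(m.group(2))
    m = _ATOM_RE.fullmatch(token)
    if m and m.group(2) in VALENCES:
        return "atom", _BOND_PREFIX[m.group(1)], m.group(2)
    return "other", 0, None


def _index_value(token: str) -> int:
    return _INDEX_OF.get(token, 0)


@dataclass
class DecodedGraph:
    """Molecular graph derived from a token sequence, with provenance."""

    elements: list[str] = field(default_factory=list)
    #: (atom_a, atom_b, order, source token position)
    bonds: list[tuple[int, int, int, int]] = field(default_factory=list)
    #: per input token: consumed role
    roles: list[str] = field(default_factory=list)
    #: source token position of each atom
    atom_source: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def decode_graph(tokens: list[str]) -> DecodedGraph:
    """Derive a molecular graph from SELFIES tokens (never fails)."""
    n = len(tokens)
    g = DecodedGraph(roles=["unused"] * n)
    free: list[int] = []  # remaining valence per atom
    bond_key: dict[tuple[int, int], int] = {}  # pair -> index into g.bonds

    def add_bond(a: int, b: int, order: int, src: int) -> int:
        key = (min(a, b), max(a, b))
        if key in bond_key:
            i = bond_key[key]
            aa, bb, old, s0 = g.bonds[i]
            order = min(order, 3 - old)
            if order <= 0:
                return 0
            g.bonds[i] = (aa, bb, old + order, s0)
        else:
            bond_key[key] = len(g.bonds)
            g.bonds.append((a, b, order, src))
        free[a] -= order
        free[b] -= order
        return order

    def derive(pos: int, end: int, head: int | None, state: int) -> None:
        """Derive a chain from tokens[pos:end] attached to ``head``.

        ``state`` is the maximum order of the next bond from ``head``
        (ignored when head is None, i.e. at the very start).
        """
        while pos < end:
            if head is not None and state <= 0:
                # attachment atom saturated: rest of this span is inert
                pos += 1
                continue
            tok = tokens[pos]
            kind, order, payload = _classify(tok)
            if kind == "atom":
                elem = payload
                cap = VALENCES[elem]
                if head is None:
                    b = 0
                else:
                    b = min(order, state, cap)
                g.elements.append(elem)
                g.atom_source.append(pos)
                free.append(cap)
                new = len(g.elements) - 1
                if head is not None:
                    add_bond(head, new, b, pos)
                g.roles[pos] = "atom"
                head = new
                state = min(3, free[new])
                pos += 1
            elif kind == "branch":
                size = payload
                if head is None or state <= 1 or free[head] <= 1:
                    g.roles[pos] = "skipped"
                    pos += 1
                    continue
                if pos + 1 + size > end:
                    g.roles[pos] = "skipped"
                    pos += 1
                    continue
                g.roles[pos] = "branch"
                q = 0
                for i in range(size):
                    q = q * 16 + _index_value(tokens[pos + 1 + i])
                    g.roles[pos + 1 + i] = "index"
                body_start = pos + 1 + size
                body_end = min(body_start + q + 1, end)
                branch_state = min(order, state - 1, free[head] - 1)
                derive(body_start, body_end, head, branch_state)
                state = min(3, free[head])
                pos = body_end
            elif kind == "ring":
                size = payload
                if head is None:
                    g.roles[pos] = "skipped"
                    pos += 1
                    continue
                if pos + 1 + size > end:
                    g.roles[pos] = "skipped"
                    pos += 1
                    continue
                g.roles[pos] = "ring"
                q = 0
                for i in range(size):
                    q = q * 16 + _index_value(tokens[pos + 1 + i])
                    g.roles[pos + 1 + i] = "index"
                target = max(0, len(g.elements) - 1 - (q + 1))
                if target != head:
                    b = min(order, free[head], free[target])
                    if b >= 1:
                        add_bond(head, target, b, pos)
                state = min(3, free[head])
                pos += 1 + size
            else:
                # unknown / start / pad token: skipped for robustness
                g.roles[pos] = "skipped"
                pos += 1

    derive(0, n, None, 0)
    return g


_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


def _graph_to_mol(g: DecodedGraph) -> Chem.Mol | None:
    if g.n_atoms == 0:
        return None
    rw = Chem.RWMol()
    for elem in g.elements:
        rw.AddAtom(Chem.Atom(elem))
    for a, b, order, _src in g.bonds:
        rw.AddBond(a, b, _BOND_TYPE[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def decode_to_mol(s: str | list[str]) -> Chem.Mol | None:
    """Decode a SELFIES string (or token list) to an RDKit molecule.

    Returns None for atom-less derivations (e.g. a string made only of
    special tokens).
    """
    tokens = tokenize_selfies(s) if isinstance(s, str) else list(s)
    return _graph_to_mol(decode_graph(tokens))


def decode_selfies(s: str | list[str]) -> str | None:
    """Decode to a canonical SMILES string, or None for the empty molecule."""
    mol = decode_to_mol(s)
    return Chem.MolToSmiles(mol) if mol is not None else None


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------


def _require_supported(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in VALENCES:
            raise SelfiesError(f"unsupported element {atom.GetSymbol()}")
        if atom.GetFormalCharge() != 0:
            raise SelfiesError("charged atoms are not supported")
        if atom.GetIsotope() != 0:
            raise SelfiesError("isotopes are not supported")
        if atom.GetNumRadicalElectrons() != 0:
            raise SelfiesError("radicals are not supported")


def _atom_token(elem: str, incoming_order: int) -> str:
    return f"[{_PREFIX_OF_ORDER[incoming_order]}{elem}]"


def _index_tokens(q: int, size: int) -> list[str]:
    digits = []
    for _ in range(size):
        digits.append(INDEX_ALPHABET[q % 16])
        q //= 16
    return digits[::-1]


def _sized_symbol(base: str, order: int, q: int) -> tuple[str, list[str]]:
    """Pick RingL/BranchL size for an index value and build its tokens."""
    for size in (1, 2, 3):
        if q < 16**size:
            return f"[{_PREFIX_OF_ORDER[order]}{base}{size}]", _index_tokens(q, size)
    raise SelfiesError(f"index value {q} too large")


def encode_selfies(smiles: str) -> str:
    """Encode a SMILES string as SELFIES tokens.

    The traversal follows the atom order of the input SMILES (depth first,
    lower-index children first, side chains as branches), so the printed
    encodings of common ring fragments are reproduced verbatim.
    """
    return "".join(encode_selfies_tokens(smiles))


def encode_selfies_tokens(smiles: str) -> list[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesError(f"cannot parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise SelfiesError("empty molecule")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SelfiesError("multi-fragment molecules are not supported")
    _require_supported(mol)
    rw = Chem.RWMol(mol)
    Chem.Kekulize(rw, clearAromaticFlags=True)

    order_of = {}
    for bond in rw.GetBonds():
        o = int(bond.GetBondTypeAsDouble())
        if o not in (1, 2, 3):
            raise SelfiesError("only single/double/triple bonds are supported")
        key = (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        order_of[key] = order_of[(key[1], key[0])] = o


    nbrs = {
        a.GetIdx(): sorted(n.GetIdx() for n in a.GetNeighbors())
        for a in rw.GetAtoms()
    }

    # pass 1: DFS tree structure (children in index order, back edges at the
    # later-visited endpoint)
    tree_children: dict[int, list[int]] = {i: [] for i in nbrs}
    back_edges: dict[int, list[int]] = {i: [] for i in nbrs}
    rank: dict[int, int] = {}

    def explore(a: int, parent: int | None) -> None:
        rank[a] = len(rank)
        for b in nbrs[a]:
            if b == parent:
                continue
            if b in rank:
                back_edges[a].append(b)
            else:
                tree_children[a].append(b)
                explore(b, a)

    explore(0, None)
    if len(rank) != rw.GetNumAtoms():
        raise SelfiesError("disconnected molecule")
    # each cycle edge is seen from both endpoints; a ring-closure token is
    # emitted only at the later-visited one
    for a in back_edges:
        back_edges[a] = [b for b in back_edges[a] if rank[b] < rank[a]]

    # pass 2: emit tokens; derivation position = pre-order rank
    pos: dict[int, int] = {}
    counter = [0]

    def emit(a: int, incoming: int) -> list[str]:
        pos[a] = counter[0]
        counter[0] += 1
        toks = [_atom_token(rw.GetAtomWithIdx(a).GetSymbol(), incoming)]
        for b in back_edges[a]:
            q = pos[a] - pos[b] - 1
            sym, idx = _sized_symbol("Ring", order_of[(a, b)], q)
            toks += [sym] + idx
        children = tree_children[a]
        for i, c in enumerate(children):
            sub = emit(c, order_of[(a, c)])
            if i < len(children) - 1:
                sym, idx = _sized_symbol("Branch", order_of[(a, c)], len(sub) - 1)
                toks += [sym] + idx + sub
            else:
                toks += sub
        return toks

    tokens = emit(0, 1)
    # hydrogens are implicit in this dialect, so e.g. hypervalent [SH]
    # cannot be represented; verify the encoding decodes back to the
    # input structure and refuse to emit a lossy string
    if decode_selfies(tokens) != Chem.MolToSmiles(mol):
        raise SelfiesError(f"structure not representable losslessly: {smiles!r}")
    return tokens
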