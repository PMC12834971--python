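"""Tokenise molecular strings, convert between schemes, build windows.

SMILES is compact but fragile (an arbitrary string rarely parses);
SELFIES is an automaton encoding in which every token string decodes to
a molecule.  Training operates on fixed-length windows: start token
inserted, pads on both sides.
"""

import numpy as np

from bidirmol.codecs import (Scheme, build_vocabulary, convert_encoding,
                             encode_window, is_valid, strip_special,
                             tokenize)

smiles = "C1=CC=NC=C1"  # pyridine
selfies = convert_encoding(smiles, Scheme.SMILES, Scheme.SELFIES)
print(f"pyridine SMILES : {smiles}")
print(f"pyridine SELFIES: {selfies}")
print(f"SMILES tokens   : {tokenize(smiles, Scheme.SMILES)}")

# any token soup is a valid molecule in SELFIES, unlike SMILES
print("random SELFIES valid?", is_valid("[Ring1][C][=O][Branch1][N][C]",
                                        Scheme.SELFIES))
print("truncated SMILES valid?", is_valid("C1=CC", Scheme.SMILES))

tokens = tokenize(selfies, Scheme.SELFIES)
vocab = build_vocabulary([tokens], Scheme.SELFIES)
window = encode_window(tokens, vocab, m_total=12, placement="fixed",
                       rng=np.random.default_rng(0))
print("window ids      :", window.token_ids.tolist(),
      f"(start token at {window.start_offset})")
print("stripped        :", strip_special(window, vocab) == selfies)
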