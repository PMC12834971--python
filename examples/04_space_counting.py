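"""How much larger is the space a bidirectional model can reach?

For a seed of N tokens in a window of M positions over an L-token
alphabet, one-sided growth reaches L^(M-N) strings while two-sided
growth also chooses the seed position: L^(M-N) * (M-N+1) minus a small
repeat correction.  The exact count comes from a pattern-matching
automaton dynamic programme, verifiable by brute force at small sizes.
"""

from bidirmol.chem_space import (SpaceQuery, bi_dominant_count,
                                 bi_exact_count, brute_force_count,
                                 space_counts, uni_count)
from bidirmol.codecs import Scheme, tokenize
from bidirmol.fixtures import bundled_seeds

# tiny instance, checkable by hand: strings of length 4 over {a, b}
# containing "ab"
counts = space_counts(["a", "b"], ["a", "b"], 4)
brute = brute_force_count(["a", "b"], ["a", "b"], 4)
print(f"toy instance: uni={counts.uni} bi_dominant={counts.bi_dominant} "
      f"bi_exact={counts.bi_exact} (enumeration: {brute})")

# database-scale: SELFIES windows of 83 tokens over a 33-token alphabet
L, M = 33, 83
print(f"\nseed fragments in an {M}-token window, {L}-token alphabet:")
print(f"{'seed':14s} {'N':>3s} {'|D_uni|':>12s} {'|D_bi| / |D_uni|':>18s}")
for frag in bundled_seeds():
    n = len(tokenize(frag.selfies, Scheme.SELFIES))
    q = SpaceQuery(L=L, M=M, N=n)
    ratio = bi_dominant_count(q) / uni_count(q)
    print(f"{frag.name:14s} {n:3d} {float(uni_count(q)):12.3e} "
          f"{ratio:18.0f}")
print("\n(the ratio is exactly M - N + 1: the number of legal positions)")
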