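# Methods

This note records the modelling choices, default parameters, numerical
conventions and known limitations of the package. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## String encodings and the bundled SELFIES codec

Molecules are handled as SMILES or SELFIES token strings. SMILES tokens come
from an ordered regular expression (bracket atoms, `%nn` ring closures,
two-letter halogens, single atoms, bond/branch/ring symbols); multi-character
atoms are atomic tokens, a deliberate choice where either convention would
work. SELFIES tokens are the bracketed units.

The package bundles its own SELFIES-dialect codec rather than depending on an
external one. The decoder is a derivation automaton: atom tokens bond to the
current attachment atom with order `min(prefix, remaining valence of both
partners)`; `[BranchL]`/`[RingL]` symbols read L hexadecimal index tokens
(16-symbol index alphabet, any unknown token counting as 0) giving the branch
length or ring reach; special tokens that cannot apply in the current state
are skipped. Consequently *every* token string derives a valid molecule —
the property the SELFIES scheme exists for — with atom-less derivations
(strings of only special tokens) decoding to nothing. Valence caps: B 3, C 4,
N 3, O 2, P 5, S 6, halogens 1; neutral atoms only, no isotopes, charges,
radicals or stereochemistry. Hydrogens are implicit, so structures whose
hydrogen counts RDKit would not reassign (e.g. hypervalent `[SH]`) are not
representable; the encoder decodes its own output and raises rather than emit
a lossy encoding. The decoder records per-token provenance (the role each
token was consumed in, and which atoms/bonds each token produced), which the
constrained-generation filter relies on.

## Windows, start/pad protocol, and the four variants

Training and generation use fixed-length windows: the token sequence with one
start token (`G`/`[G]`) inserted — middle of the core (`fixed`), a uniform
position (`random`), or an end (`left`/`right`, the layouts of the purely
forward/backward models) — padded symmetrically with `A`/`[A]`. Pads are
restricted to a contiguous prefix and suffix, so stripping specials inverts
the construction exactly. Window length is a configuration parameter; the
drug-database-scale values are 76 (SMILES) and 83 (SELFIES) tokens, while
synthetic fixtures use ~15-30.

All variants share a two-layer LSTM core between batch-normalisation layers
(5-layer plan: BatchNorm, LSTM, LSTM, BatchNorm, Linear; BIMODAL has 7 layers
with paired forward/backward LSTMs). Inputs are one-hot token vectors — no
learned embedding table. Batch normalisation acts on the feature dimension,
pooling batch and time steps in training mode; during generation and RL
rollouts it uses frozen running statistics, so every logit is a deterministic
function of (weights, input). Hidden size defaults to 1024 (the scale used
with a sixfigure training corpus); fixture-scale runs use 32-128. Weights
initialise from the standard uniform fan-in distribution under a configured
seed.

Emission schedules:

* **forward/backward** — next-token prediction in reading order; the backward
  model is the same network run on reversed strings (the mirror identity is
  tested by weight transplant).
* **FBRNN** — reads the synchronised token pair `(w[g-t], w[g+t])` outward
  from the start position g (out-of-window reads clamp to pad) and predicts
  the pair `(w[g-t-1], w[g+t+1])` from the two halves of a doubled-width
  linear output. Two tokens per iteration.
* **BIMODAL** — position p's logits combine the forward state over
  `w[0..p-1]` and the backward state over `w[p+1..M-1]` through one linear
  head. Training supervises every non-start position of the full window (the
  bidirectional-reader teacher forcing); generation alternates sides (step 1
  rightward), re-reading the current window before each emission, so the
  outer context at generation time is pads. This train/generate context
  asymmetry is inherent to the scheme and is accepted as such.

There is no end-of-string token: a side that samples pad is frozen (further
emissions forced to pad) and generation always runs to the window edges, then
strips. Teacher forcing supervises pad targets like any others — that is how
the models learn to stop.

## Maximum-likelihood training

Adam at learning rate 1e-3 (MLE defaults are not dictated by the published
protocol and are exposed in configuration), mean cross-entropy over the
variant's emission schedule, mean over batch. k-fold cross-validation
(default 5 folds, 10 epochs; fixture runs use 2 x 2) trains one model per
fold with per-(fold, epoch) checkpoints; `random` start placement re-samples
the position each epoch as a form of augmentation. A NaN loss aborts with a
diagnostic. Gradients come from a small bundled reverse-mode autodiff engine
over float64 numpy arrays; its correctness is pinned by finite-difference
checks (1e-4) and a scalar-by-scalar LSTM-cell oracle (1e-6) in the test
suite.

## Constrained generation and seed validity

A seed constraint replaces the lone start token; `fixed` placement centres
it. Seeds should be aperiodic token lists whose two terminal atoms keep an
open valence — `validate_seed` diagnoses decodability, terminal hydrogen
counts, and periodicity. The six bundled fragments (indole, pyridine,
benzimidazole, piperazine, amide, quinoline) all pass.

A constrained result is **valid** only if the seed survived decoding intact:

* SMILES: the core parses and the decoded molecule has the seed as an RDKit
  substructure match;
* SELFIES: decoder provenance shows every seed token consumed in its
  original role, the seed atoms carrying exactly their original internal
  bonds, and no attachment bond closing a new ring through the seed. The last
  rule exists because a generated bridge that fuses the seed into a larger
  ring system changes the seed's perceived aromaticity (~0.3% of raw samples
  in toy runs), which would break the substructure guarantee; such samples
  are discarded exactly like valence-rule clobberings.

`sample_filtered` draws until the requested number of unique (raw-string
level), valid, novel results accumulate, with an attempt cap of 50x the
target. Novelty is judged at the canonical-structure level against the
training set — string-level novelty would miscount trivially re-encoded
duplicates; the uniqueness stage stays at string level, matching the metric
chain definition (valid among unique, novel among valid).

## Rewards and REINFORCE fine-tuning

The terminal reward is `R = Σ_l w_l p_l` over registered property scorers:
`qed` (RDKit QED, [0,1]) and `sa` (Ertl-Schuffenhauer synthetic
accessibility from RDKit's contrib tree, clamped to [1,10] then rescaled to
`-(SA-1)/9 ∈ [-1,0]`). Scores exist only for finished strings, so per-step
rewards are zero before the terminal step; an invalid molecule earns 0 — a
neutral fallback that keeps the reward range aligned with the rescaled
terms, rather than a negative penalty.

Fine-tuning defaults follow the published protocol: K=32 rollouts per
episode at T=1.0, AdamW (decoupled decay 1e-2) at learning rate 1e-4,
entropy coefficient 1e-4, 120 episodes, optional early stop when a
10-episode moving average of the batch reward stalls (patience 20, tolerance
1e-3 — the stopping rule needs a tolerance the protocol does not state).
Desk-scale runs in the tests and examples use learning rate 1e-3: with a
64-hidden toy model over ~100 episodes the 1e-4 step size (calibrated for a
1024-hidden model) produces no measurable property movement.

The gradient is taken on the surrogate
`(1/K) Σ_i log π(a^i) (R^i − R̄₋ᵢ) + β (1/K) Σ_i Σ_t H_t^i`, with the
per-trajectory log-probability summed over steps and entropy summed over
steps and averaged over the batch. The baseline subtracted from trajectory i
is the **leave-one-out** batch mean: a baseline must be independent of the
trajectory's own actions to leave the estimator unbiased, and the
self-inclusive batch mean shrinks the gradient by (K−1)/K. Algebraically the
leave-one-out form equals the self-inclusive one with advantages scaled by
K/(K−1), so the two differ only by a constant absorbed into the learning
rate. Seed-constrained rollouts force the seed tokens, which contribute
neither log-probability nor entropy. Batch-norm statistics stay frozen
throughout RL.

## Reachable-space counting

`L^(M−N)` for one-sided growth; `L^(M−N)·(M−N+1)` as the dominant two-sided
term (positions x completions). The exact count of length-M strings
containing the pattern is computed by a Knuth-Morris-Pratt failure-function
automaton dynamic programme in O(M·N·L) with arbitrary-precision integers,
rather than a closed-form repeat-correction series, because the DP is
directly verifiable: the test suite checks it against exhaustive enumeration
for every pattern of length ≤ 3 over alphabets of size ≤ 3 and M ≤ 10, plus
the sandwich `uni ≤ exact ≤ dominant` and the exact ratio
`dominant/uni = M−N+1`. The aperiodicity precondition (no proper divisor
period tiles the pattern) is checked separately.

## Evaluation battery

Unique/valid/novel percentages are a chain (distinct among sampled, valid
among distinct, novel among valid). The distribution tests are two-sided
Mann-Whitney U and two-sample Kolmogorov-Smirnov from scipy, no
multiple-testing correction, with identical constant samples defined as
p = 1. Fingerprints are 2048-bit Morgan, radius 2 (the bit length is the
stated convention; the radius is the common ECFP4-equivalent default).
2-D embedding delegates to scikit-learn's t-SNE (default perplexity 30,
seeded); the package owns only the fingerprints and the labelled export.

## Synthetic data: what it emulates and what it does not

`make_toy_corpus` draws random SELFIES token strings over a restricted
alphabet (`[C] [=C] [N] [=N] [O] [=O] [Branch1] [=Branch1] [Ring1]`),
decodes them (valid by construction), de-duplicates at the canonical level,
and re-encodes the canonical structure — emulating a curated corpus where
each molecule appears once in a canonical encoding. Defaults: 500 molecules
of 5-14 tokens, seeded. This reproduces the *structural* properties the
package's claims rest on (small organic molecules, rings and branches, a
closed vocabulary) but not the size, property distributions or chemotype
diversity of a real drug database: toy corpora have systematically lower QED
(~0.3-0.5) and a narrow scaffold range. Tests passing on these fixtures
certify the machinery — encoding round trips, schedule correctness, seed
preservation, the direction of RL optimisation — not the absolute metric
values a database-scale run would produce (uniqueness/novelty percentages
and distribution-test p-values at that scale are corpus properties, out of
desk-scale reach).

## Numerical conventions and degenerate inputs

All offsets are 0-based with half-open intervals; every source of
randomness is an injected `numpy.random.Generator`. Temperature softmax is
max-stabilised; entropy uses natural log with 0·log 0 = 0. Sampling uses
inverse-CDF draws on the cumulative distribution with a top-end guard.
Categorical edge cases are defined explicitly: empty corpora, empty seeds,
out-of-range SA inputs, all-zero reward weights, and batches of fewer than
two trajectories are rejected with errors; equal-reward batches produce an
exactly zero policy gradient.

## Known limitations

* The SELFIES dialect covers neutral organic-subset chemistry only; charged
  or stereochemically annotated seeds are rejected rather than mis-encoded.
* Alternative encodings of the same seed structure (which would expose other
  attachment points) are not enumerated.
* BIMODAL training context is the full window while generation sees pads
  beyond the frontier (inherent to the published scheme).
* The SA score is a heuristic; RL can exploit its blind spots (e.g. large
  macrocycles scored as accessible), a property of the reward, not the
  optimiser.
* Fréchet ChemNet Distance is not computed (it needs a pretrained network);
  the evaluation module's interfaces accept an external callable instead.
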