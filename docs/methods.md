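# Methods

## The problem and the representation

Porous organic cages (POCs) are discrete molecules with an internal cavity
reachable through windows. A cage is useful as a porous material only if it
is *shape-persistent*: the cavity must survive removal of the solvent.
Whether a given precursor combination yields a persistent or a collapsed
cage is expensive to establish (conformer search by molecular dynamics plus
cavity analysis), which motivates a generative model that proposes new
cages biased toward persistence.

The package works on cages of Tri⁴Di⁶ topology — four tri-topic vertex
precursors (BB1) and six di-topic edge precursors (BB2) joined by one
dynamic covalent reaction. Instead of one very long SMILES for the
assembled cage, a cage is stored *disassembled* as the triple

    (BB1 catalog ordinal, BB2 SMILES with two [Lr] site tokens, reaction ordinal)

plus an optional binary shape-persistence label. Only the BB2 is free text;
BB1 skeletons and reactions are closed catalogs, so two of the three
components can never be generated invalid. The `[Lr]` placeholder (an
element token unused by organic chemistry) marks the two reactive
end-group attachment points of the edge precursor; a generated BB2 is a
usable precursor exactly when it parses and carries two such sites.

Raw persistence labels come in three levels (collapsed / not collapsed /
undetermined); `relabel` folds *undetermined* into *collapsed* so the
target is binary, the pessimistic choice for ambiguous cages. Numerically
the predictor outputs the probability of **collapse** (label 1 =
collapsed).

## Tokenisation

The BB2 tokeniser is character-level over a closed vocabulary: the four
specials `[pad] [sos] [eos] [Lr]` always occupy indices 0–3, followed by
the corpus tokens in lexicographic order. Multi-character tokens (`Cl`,
`Br`, bracket atoms such as `[nH]`) are replaced by single-character
surrogates from a fixed, versioned table before indexing and expanded back
on decoding; this keeps the sequence model strictly character-level while
staying reversible. Sequences are wrapped in `[sos]`/`[eos]` and padded to
a fixed maximum length.

## Symmetry as a graph property

Tri⁴Di⁶ assembly wants C₂-symmetric edge precursors. Molecular point-group
symmetry is approximated by graph symmetry: a BB2 counts as symmetric when
its two site atoms lie in the same automorphism orbit of the heavy-atom
molecular graph, with nodes coloured by element and edges by bond order
(hydrogens implicit). The implementation searches for a colour-preserving
automorphism exchanging the two sites (VF2 on the canonical form); the test
suite checks it against an independent exhaustive backtracking enumeration
and against canonical-rank symmetry classes.

## Model

A multi-component VAE encodes the three cage components into one
128-dimensional latent space (16 at desk scale):

- **Sequence branch** — token embeddings feed a bidirectional GRU; the
  final hidden states of both directions summarise the BB2.
- **Categorical branch** — one-hot BB1 and reaction ordinals feed a small
  MLP.
- The concatenated summaries pass through two affine heads giving the mean
  and log-variance of a diagonal-Gaussian posterior q(z|X); the prior is
  standard normal.

Decoding mirrors the split: a single-direction GRU (hidden state
initialised from z, and z concatenated to every input embedding) emits BB2
tokens autoregressively from `[sos]` until `[eos]`; an MLP with two
softmax heads reconstructs BB1 and reaction, so generation cannot leave the
catalogs. An MLP predictor with heavier dropout maps z to the collapse
probability.

The objective is the weighted sum

    L = w_bb2·CE(bb2 tokens) + w_bb1rxn·(CE(bb1)+CE(rxn)) + β·KL + γ·BCE_masked

with CE a softmax cross-entropy (per-token mean over non-pad positions for
the sequence) and the predictive binary cross-entropy masked to labeled
records only — unlabeled cages contribute exactly nothing to that term,
which is what makes semi-supervised training on a mostly unlabeled
augmented pool possible. With β = γ = 0 the objective reduces to a plain
autoencoder. The reconstruction weights default to w_bb2 = w_bb1rxn = 1.

The network is implemented on a small reverse-mode automatic
differentiation engine over NumPy arrays (`_autodiff.py`, `_nn.py`) whose
gradients are verified against finite differences in the test suite.

## Training protocol

Full-scale defaults: 100 epochs, batch 64, Adam at 1e-4, β = 0.0025,
γ = 1. Two schedulers shape the loss over training:

- **Cyclic β annealing** — β rises linearly from 0 to its maximum over the
  first half of each of 5 cycles, then holds the maximum; restarting the
  ramp counteracts KL vanishing in autoregressive decoders. The ramp
  fraction defaults to 0.5 and β is constant within an epoch.
- **Linear weight** — epoch/(epochs−1), applied to both the BB1+reaction
  reconstruction component and the predictor term, so early training
  prioritises the BB2 sequence.

The split is greedy: floor(0.900·N) of the original and floor(0.998·N) of
the augmented records train; the complements are the two held-out sets
(loss/accuracy monitoring on the original one, reconstruction on the
augmented one). Labeled and unlabeled records mix uniformly into every
batch. The predictor sees sampled z during training and posterior means at
evaluation. Gradients are clipped to a global L2 norm of 5 — the recurrent
decoder occasionally produces exploding steps at desk-scale learning rates.
A non-finite loss aborts training immediately.

### Desk scale

The test suite and the acceptance script train on synthetic datasets of
500 cages. The desk-scale preset (`presets.py`) uses latent 16, hidden
64/128, embedding 32, 30 epochs, batch 16, learning rate 5e-3 with cosine
decay to a tenth of the initial rate, and dropout
0.05/0.1. These are the package's own choices for that data volume: at 500
records the full-scale dropout (0.25/0.5) is far too strong a regulariser
and 1e-4 far too slow a rate for a 30-epoch schedule; the schedulers, β
maximum and split fractions are unchanged from full scale.

## Generation strategies

- **Prior sampling** draws z ~ N(0, I) and decodes greedily.
- **Repeated reconstruction** encodes one cage, draws many z from its
  posterior and decodes each — the frequency table (with mean latent
  distance per decoded cage) probes how tightly the model has localised
  the cage.
- **Interpolation** connects the posterior means of two cages by slerp
  (default) or lerp. For conditional generation the start cage must have a
  predicted persistence probability of at least the threshold (default
  0.8); decoded path points at or above the threshold are kept.
- **Bayesian optimisation** minimises the acquisition
  `−log p(y=t|z) + ω·‖z‖²/2` with t = 0 (persistent) inside the box
  spanned per dimension by the training latents. The regulariser is the
  negative log standard-normal density (constant dropped); probabilities
  are clamped to [1e−6, 1−1e−6] so the value is finite everywhere; ω
  defaults to 0.1. The optimiser is a Gaussian-process surrogate
  (Matérn 5/2, expected improvement maximised over quasi-random candidates
  with a local polish on the surrogate); a multi-start L-BFGS-B fallback on
  the acquisition itself is available as `method="gradient"`.

Decoded candidates pass a five-stage filter in fixed order — validity,
novelty (by canonical cage key against a reference set), precursor
validity, reaction-site count, symmetry — with a resampling feedback loop
until the requested number of cages pass or the attempt budget is
exhausted. Batch quality is reported as validity over all samples;
novelty (against the original and the combined original+augmented
references separately), uniqueness and precursor validity conditioned on
the valid samples; symmetry conditioned on the precursor-valid ones.

## Synthetic data

The fixture generator emulates the schema of a curated POC dataset without
simulating any chemistry. BB2 skeletons are assembled from a grammar —
`[Lr]·arm·core·arm·[Lr]` with divalent cores (disubstituted benzenes,
2,5-heteroles, biphenylene, cyclohexylene, plain chains) and palindromic
arm pieces — which guarantees parseability and exactly two sites; mirror
arms on orbit-equivalent cores give C₂-symmetric products, and candidates
are bucketed by the symmetry predicate until the requested symmetric
fraction (default 0.7) is exact. Labels follow a deterministic rule of the
disassembled representation: a cage collapses iff its BB2 is small (fewer
than 18 heavy skeleton atoms at the default threshold, chosen to give a
roughly balanced label distribution on the default grid) or ring-free,
except under the designated rigid reaction, which always persists. Because
the rule is a function of the inputs alone, a perfectly trained predictor
could reach accuracy 1.0, so predictor-recovery tests are meaningful. A
configurable fraction of labels (default 0.3) is blanked to exercise the
semi-supervised masking.

What the fixtures do **not** emulate: MD-derived labels with noise and
class overlap, the skew and redundancy of real precursor libraries, and
corpus sizes beyond a few hundred cages. Passing the desk-scale tests
therefore demonstrates that the machinery (representation, objective,
schedulers, samplers, filters) works and can recover a known
structure-property rule — not that the model reproduces full-scale
generation or prediction quality, which depends on training with ~10⁶
cages.

## Numerical choices and degenerate inputs

- Weights are Glorot-initialised; recurrent maps are orthogonal (QR of a
  Gaussian matrix, sign-corrected), which keeps hidden dynamics
  well-conditioned and reduces seed-to-seed variance.
- Posterior sampling uses z = μ + exp(log σ²/2)·ε; the log-variance head is
  unconstrained, and KL uses the closed diagonal-Gaussian form averaged
  over the batch.
- Cross-entropies are computed through a shifted log-softmax; the
  predictive BCE clamps probabilities by 1e−12.
- slerp falls back to lerp when the angle between endpoints is below 1e−7;
  zero endpoints are rejected.
- Vocabulary ordering ties are broken lexicographically; the
  canonicalisation backend's output is taken as the canonical SMILES form.
- An all-unlabeled batch is legal (predictive term 0); an all-pad decoded
  body detokenises to the empty string and fails filter validity.
- Degenerate optimisation boxes (min = max on a dimension) are rejected at
  configuration time.

## Known limitations

- Desk-scale training cannot reproduce full-scale generation rates or
  predictor accuracy; the package reports what its own runs compute.
- The combinatorial augmentation grammar is a reconstruction from the
  stated design intent (di-topic skeletons from cores and decorations);
  equivalence to any specific published augmented pool is not claimed.
- The surrogate table covers the multi-character tokens produced by the
  built-in grammar and common halogen/charged-atom tokens; exotic bracket
  atoms are rejected rather than silently mis-tokenised.
- Bayesian optimisation cost grows cubically with the number of evaluated
  points (GP fit); at full latent dimension (128) the box search is slow
  and the gradient fallback is the practical choice.
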