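# cagevae

Generative design of shape-persistent porous organic cages (POCs).

A porous organic cage is a discrete molecule whose internal cavity,
reachable through windows, survives solvent removal only if the cage is
*shape-persistent*. Establishing persistence for a candidate cage requires
expensive molecular-dynamics conformer searches, so exploring the space of
precursor combinations calls for a generative model biased toward
persistent cages.

`cagevae` implements a multi-component variational autoencoder over the
*disassembled* representation of Tri⁴Di⁶ cages: a categorical tri-topic
vertex precursor (BB1), a SMILES-encoded di-topic edge precursor (BB2)
carrying two `[Lr]` reactive-site tokens, and a categorical reaction type.
A bidirectional GRU (sequence branch) and an MLP (categorical branch) are
fused into a diagonal-Gaussian posterior over a shared latent space z; a
GRU decoder and categorical heads reconstruct the components, and an MLP
predictor jointly trained through a semi-supervised mask estimates the
collapse probability from z. The training objective is

    L = w_bb2·CE(BB2) + w_bb1rxn·(CE(BB1) + CE(rxn)) + β·KL(q(z|X) ‖ N(0,I)) + γ·BCE_masked

with cyclic annealing of β (against KL vanishing) and a linear 0→1 weight
on the categorical and predictor terms. Trained models support prior
sampling, repeated reconstruction, lerp/slerp interpolation with a
persistence threshold, and latent Bayesian optimisation of the acquisition
`−log p(y=0|z) + ω‖z‖²/2` inside the box spanned by the training latents —
all routed through a five-stage filter (validity → novelty → precursor
validity → reaction sites → symmetry).

The neural network runs on a small reverse-mode autodiff engine over NumPy
(gradients are verified against finite differences in the test suite);
chemistry goes through RDKit, graph symmetry through a colour-preserving
automorphism search.

## Worked example

Train a desk-scale model on a synthetic cage dataset (500 cages, labels
from a known deterministic rule, 30% unlabeled), then evaluate and sample:

```python
from cagevae import CageVAE
from cagevae.presets import FIXTURE_MODEL_KWARGS, fixture_train_config
from cagevae.synthetic import FixtureSpec, make_dataset

records, bb1, reactions = make_dataset(FixtureSpec())
model = CageVAE(records, bb1_catalog=bb1, reaction_catalog=reactions,
                **FIXTURE_MODEL_KWARGS)
results = model.fit(fixture_train_config(rng_seed=0))
print(results.summary())
print("held-in reconstruction:", results.reconstruction_accuracy()["bb2_exact"])
print(results.sample_metrics(n=300, rng_seed=0).as_dict())
```

which prints (about two minutes on one CPU):

```
Cage VAE Results
==========================================================
Original records:          500
Augmented records:           0
Training records:          450
Held-out original:          50
Held-out augmented:          0
Vocabulary size:            18
Max sequence length:        45
Latent dimension:           16
Epochs trained:             30
----------------------------------------------------------
Final training losses:
  BB2 reconstruction (CE/token):      0.0163
  BB1+reaction reconstruction:        0.0209
  KL divergence:                     26.9620
  Predictor BCE (masked):             0.0052
  Weighted total:                     0.1098
Predictor accuracy (held-out original):    1.0000
==========================================================
held-in reconstruction: 0.9688888888888889
{'n_sampled': 300, 'validity': 0.76, 'novelty_original_given_valid': 0.618421052631579,
 'novelty_combined_given_valid': 0.618421052631579, 'uniqueness_given_valid': 0.868421052631579,
 'precursor_validity_given_valid': 0.9517543859649122, 'symmetry_given_precursor_valid': 0.4838709677419355}
```

Reading the output: the predictor recovers the fixture label rule exactly
on the held-out set (the rule is a deterministic function of the inputs,
so 1.0 is attainable); 97% of training cages round-trip exactly through
greedy decoding of their posterior means; and of 300 prior samples, 76%
decode to valid SMILES, ~95% of those are usable di-topic precursors (two
sites) and ~48% of those are C₂-symmetric. The rates are desk-scale
values: a 500-cage training set over a 60-skeleton BB2 pool gives the
decoder far less chemistry to generalise from than a million-cage corpus,
so validity, novelty and symmetry sit below what full-scale training
reaches.

The same pipeline is available from the shell:

```sh
cagevae fixtures --out cages.csv --catalogs-out catalogs.json --seed 0
cagevae train --dataset cages.csv --catalogs catalogs.json --checkpoint-out model.npz --seed 0
cagevae sample --checkpoint model.npz --dataset cages.csv --out samples.csv --n 100 --filtered
cagevae metrics --checkpoint model.npz --dataset cages.csv --n 500 --out report.json
```

plus `augment`, `evaluate`, `interpolate` and `optimize`; every run writes
a JSON manifest (seed, config, input digests) for reproducibility.

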