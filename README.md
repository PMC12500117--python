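# molscale

Multi-scale geometric self-supervised pre-training for 3D molecular graphs.

Molecular properties depend on geometry at several length scales at once:
direct bonding contacts (≈1–2 Å), functional-group arrangements (≈2–5 Å) and
overall conformer shape (>5 Å). Encoders that treat all interatomic
distances uniformly blur these regimes together. `molscale` implements a
pre-training framework that keeps them separate and then measures, in
information-theoretic terms, how much each scale contributes to the learned
representation. It is aimed at researchers prototyping 3D molecular
representation learning who want a dependency-light, fully inspectable
implementation that runs on a single CPU with synthetic conformers — no
external corpora, no GPU.

## The model

A molecule is a graph 𝒢 = (𝒱, ℰ, X, R) with per-atom features X and 3D
coordinates R (Å). The encoder stacks message-passing layers of
**distance-gated multi-head attention**: head assigned to scale *k* computes

    α_ij^k = softmax_j [ (W_Q^k h_i)ᵀ(W_K^k h_j) / √d · g_k(d_ij) ]

where d_ij = ‖r_i − r_j‖ and g_k is a smooth gate of distance. The reference
gate is the transition sigmoid g_k(d) = σ(β_k(d − μ_k)) with characteristic
distances μ = (1.5, 3.5, 7.0) Å; the default is a band-pass variant
σ(β(d−lo))·(1−σ(β(d−hi))) over each scale's band, which — unlike a monotone
gate — can peak *on* the middle band (see `docs/methods.md`). Because
coordinates enter only through distances, all outputs are SE(3)-invariant.

Per-scale graph embeddings z₁, z₂, z₃ are pooled from the scale's attention
heads and trained with a **hierarchical InfoNCE objective**

    L_contrast = Σ_k λ_k E[ −log exp(z_kᵀz_k⁺/τ) / Σ exp(z_kᵀz_k⁻/τ) ]

with τ = 0.07, a momentum key encoder (m = 0.999), per-scale FIFO negative
queues, and learnable simplex weights λ_k (softmax-parametrized, init ⅓).
Positives are scale-matched augmentations: atomic jitter ≤0.1 Å (scale 1),
torsion-only perturbations that preserve all bond lengths and angles exactly
(scale 2), and shape-preserving conformer resampling filtered by a
radius-of-gyration band and a steric-clash proxy (scale 3). By the InfoNCE
bound, −L_k + log N lower-bounds the mutual information I(z_k; z_k⁺).

A **geometric regularizer** ties a coordinate-reconstruction head to the
reference internal coordinates:

    L_geo = Σ (‖r_i−r_j‖ − d_ij)² + γ Σ (∠_ijk − θ_ijk)² + η Σ wrap(φ_ijkl − ω_ijkl)²

with γ = 0.1, η = 0.01, angles via arccos of the normalized dot product and
signed dihedrals via the two-plane arctan2 convention. exp(−L_geo) acts as an
unnormalized conformer plausibility score.

Diagnostics: a Kraskov k-NN mutual-information estimator (calibrated against
the Gaussian closed form −½ln(1−ρ²)), an exact discrete decomposition of
cross-scale information with interaction term ΔI, and a kernel-difference
redundancy score ‖K_z − K_x‖²_F.

Everything — encoder, losses, training — runs on a small numpy reverse-mode
autodiff core (`molscale.autodiff`), so gradients are finite-difference
checkable end to end.

## Worked example

```python
import numpy as np
from molscale import (SyntheticSpec, make_synthetic, make_corpus,
                      extract_geometry_reference, geo_loss, repair_conformer)
from molscale.pipeline import TrainConfig, pretrain, encode

# 1. a trans-butane backbone with ideal geometry
g = make_synthetic(SyntheticSpec("alkane_chain", size=4, torsion_set=(180.0,)))
ref = extract_geometry_reference(g)
print("bond lengths (Å):", [round(v, 3) for v in ref.distances.values()])
print("backbone torsion (deg):", round(np.degrees(list(ref.torsions.values())[0]), 1))

# 2. desk-scale pre-training on 200 synthetic conformers
corpus = make_corpus(200, seed=0)
cfg = TrainConfig.smoke(in_dim=corpus[0].atom_features.shape[1], seed=0)
params, run = pretrain(corpus, cfg)
print("epoch losses:", [round(x, 3) for x in run.loss_curve])
print("scale weights λ:", [round(x, 3) for x in run.final_lambdas])

# 3. embed new molecules and repair a corrupted conformer
df = encode(make_corpus(3, seed=9), params, cfg.encoder)
print("embedding table:", df.shape)
noisy = g.copy_with_coords(g.coords + np.random.default_rng(1).normal(0, 0.2, g.coords.shape))
print("geo loss before repair:", round(geo_loss(noisy.coords, ref).l_total, 4))
fixed, hist = repair_conformer(noisy, ref)
print("geo loss after  repair:", f"{hist[-1]:.2e}")
```

Output:

```
bond lengths (Å): [1.54, 1.54, 1.54]
backbone torsion (deg): 180.0
epoch losses: [5.531, 5.378, 5.261, 5.21, 5.159]
scale weights λ: [0.34, 0.34, 0.319]
embedding table: (3, 161)
geo loss before repair: 0.1391
geo loss after  repair: 1.28e-11
```

The ideal-geometry generator reproduces its construction constants exactly
(C–C = 1.54 Å, trans torsion 180°). Over five epochs the combined
contrastive + geometric loss falls from 5.53 to 5.16 while the scale weights
stay near their uniform initialization. Gradient descent on the geometric
loss repairs a 0.2 Å-corrupted conformer back to its reference internal
coordinates (loss ~10⁻¹¹).

A CLI mirrors the library:

```bash
molscale make-synthetic --family alkane_chain --size 8 --count 50 --out mols.sdf
molscale pretrain --n-synthetic 200 --seed 0 --checkpoint model.npz
molscale encode --checkpoint model.npz --input mols.sdf --out emb.tsv
molscale diagnose-mi --embeddings emb.tsv --out mi.json
```

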