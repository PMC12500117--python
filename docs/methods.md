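# Methods

This note documents the models and procedures `molscale` implements, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Geometric scales and the gated attention encoder

Three scales partition interatomic distance: s1 = 1–2 Å (bonding contacts,
characteristic distance μ₁ = 1.5 Å), s2 = 2–5 Å (functional-group motifs,
μ₂ = 3.5 Å), s3 = >5 Å (conformer-level relationships, μ₃ = 7.0 Å). Each
attention head belongs to one scale and its logit between atoms i and j is
the scaled query–key dot product *multiplied* by the scale's distance gate,
then row-softmaxed over the neighborhood (all atoms within the 12 Å cutoff,
self included, so no row is ever empty). Multiplying the logit — rather than
masking the softmax output — keeps every row exactly stochastic and keeps
the gate differentiable inside the objective; its quirk is that a fully
closed gate (g → 0) yields a *uniform*, not zero, contribution. We keep the
multiplicative form because it is the formulation the attention weights are
defined by; the practical scale separation it achieves is measured, not
assumed (see the specialization gap below).

Gate forms. The transition sigmoid g_k(d) = σ(β_k(d − μ_k)) is monotone in
d, which makes it structurally unable to respond most strongly to the
*middle* band: any monotone gate that is high at 3.5 Å is at least as high
at 10 Å. The band-pass product σ(β(d−lo))·(1−σ(β(d−hi))) over the scale's
band edges (lo, hi) = (1,2), (2,5), (5,∞) Å fixes this and is the default;
the sigmoid form remains available (`gate_form="sigmoid"`) for fidelity.
β is initialized to 4 Å⁻¹ for all scales; β, μ and the band edges are
trainable (`learn_gates=False` freezes them).

Specialization is quantified as Δ_k = E_{d∼p_k}[g_k] − max_{j≠k} E_{d∼p_j}[g_k],
the gate's mean response on its own band's empirical distance distribution
minus its best off-band response. Positive Δ_k certifies scale focus;
band-pass gates give Δ_k > 0 for all three scales at initialization, while
the monotone sigmoid provably gives Δ₂ < 0 against distant samples — both
facts are asserted in the test suite.

Architecture plumbing that the attention definition leaves open, resolved as
standard transformer practice: per-head value projections, head concat +
output projection, residual connection and layer normalization per layer.
Reference configuration: 6 layers, hidden 256, 8 heads split 3/3/2 over
s1/s2/s3. Scale embeddings z_k are the atom-mean of the final layer's
scale-k head channels, passed through a two-layer projection head and
L2-normalized. Coordinates enter only through pairwise distances, so all
outputs are invariant under proper rigid motions and equivariant under atom
permutation (checked to 1e−5 over random motions/permutations; in practice
~1e−15).

## Contrastive objective

Per scale, InfoNCE with temperature τ = 0.07 over dot-product similarities
of L2-normalized embeddings; negatives are the other molecules' key
embeddings in the batch plus a per-scale FIFO queue (reference capacity
65,536; desk-scale runs use 512). The denominator includes the positive
term — the standard form, and the one under which −L + log N lower-bounds
I(z; z⁺); the negatives-only variant is available via
`include_positive_in_denominator=False`. The key encoder is a momentum copy
(m = 0.999). Queues are prefilled with key embeddings of augmented corpus
views before step 0 so the negative count — and hence the scale of the loss
— is constant through training; without this, the loss *rises* as the queue
fills even while the model improves, confounding any loss-trend readout.

Scale weights λ_k live on the simplex via softmax-parametrized logits
(init 0 → λ = ⅓ each) and are updated by the same Adam optimizer as the
encoder, receiving the gradient of Σ λ_k L_k. How often λ should update
relative to the encoder is not prescribed anywhere; updating jointly every
step is the simplest consistent choice.

## Augmentations (positive views)

* **Scale 1 — atomic jitter.** Independent per-atom displacements uniform in
  a ball of radius ≤0.1 Å. The bound is part of the study conditions; the
  uniform-in-ball distribution is our choice (the bound constrains magnitude,
  not shape).
* **Scale 2 — group perturbation.** Rotations about rotatable bonds only
  (acyclic bonds with both endpoints of degree ≥2), each by at most a bounded
  torsion (default 30°). Bond lengths, bond angles and all 1-2/1-3 distances
  are preserved *exactly* (rigid rotation about the bond axis), which is the
  defining property of this scale's view.
* **Scale 3 — conformer resampling.** All rotatable torsions are redrawn —
  from the molecule's construction alphabet when it is synthetic, otherwise
  from a von Mises proposal around the current value (κ = 2). A candidate is
  accepted only if its radius of gyration is within ±15 % of the original and
  no nonbonded pair (excluding 1-3 pairs, which angles already fix) comes
  closer than 0.8× the sum of covalent radii. This clash-plus-shape filter
  operationalizes "energy-aware, shape-preserving" sampling without a force
  field: it is monotone with the repulsive part of a van der Waals energy and
  dependency-free. After 50 rejections the least-clashing shape-valid
  candidate is returned and flagged in the perturbation log.

All augmentations preserve atom count, order, features and bonds, and are
deterministic per seed (numpy PCG64).

## Geometric regularization

L_geo = L_dist + γ·L_angle + η·L_torsion with γ = 0.1, η = 0.01. Sums run
over the reference's bonded tuples: bonded pairs for distances, bonded paths
i–j–k for angles, bonded paths i–j–k–l for torsions. Which tuples enter the
sums is an open choice; bonded-path enumeration keeps the loss local,
O(atoms) in size, and matches the chemical meaning of "bond angle" and
"dihedral". Predicted coordinates come from a two-layer displacement head on
the node embeddings, zero-initialized so prediction = input at step 0; the
source of predicted positions is otherwise unconstrained by the loss
definition.

Numerical choices: the arccos argument is clamped to ±(1−1e−9) so angle
gradients stay finite at collinearity; torsion residuals are wrapped to
(−π, π] before squaring so 2π-equivalent angles incur no penalty (the
unwrapped form would penalize them; wrapping preserves the intent and is the
default, `wrap_torsion=False` restores the literal form). The wrap constant
is piecewise-constant in the coordinates, so it does not perturb gradients
away from the ±π boundary. All three terms depend on coordinates only
through internal coordinates and are therefore rigid-motion invariant; L_geo
= 0 exactly on the reference conformer and any rigid motion of it.

Conformer repair optimizes coordinates directly against L_geo with Adam
(lr 0.05, 200 steps): 0.3 Å jitter on ideal alkanes is repaired to bond
lengths within 0.01 Å and angles within 0.01 rad, which is the package's
parameter-recovery check. exp(−L_geo) is reported as an unnormalized
plausibility (energy-based) score.

The combined pre-training objective is L_contrast + w_geo·L_geo with
w_geo = 1 by default; w_geo = 0 keeps the geometric terms in the logs but
out of the gradient.

## Information diagnostics

Continuous MI uses the Kraskov–Stögbauer–Grassberger estimator (k = 3,
Chebyshev metric, per-dimension standardization, 1e−10 deterministic jitter
to break exact ties). Calibration: within 0.05 nats of −½ln(1−ρ²) for
ρ ∈ {0, 0.3, 0.5, 0.8, 0.95} at n = 5000 averaged over 10 seeds (measured
error ~0.002 nats). The entropy identity I = H+H−H(joint) is not directly
computable for continuous embeddings, which is why an estimator had to be
chosen; KSG is the field's default. Self-MI diagonal entries in reports are
Kozachenko–Leonenko entropy proxies and flagged as such.

The cross-scale decomposition reports I(G_k; h), the pairwise joint terms
I(G_j,G_k; h), and ΔI = ΣI(pairs) − ΣI(singles). In discrete mode every term
is an exact plug-in value over the empirical joint and is verified against
brute-force enumeration to 1e−12. Note a property of this ΔI as defined:
when h is a copy of one scale, ΔI = +H(that scale), not 0 — redundant (not
only synergistic) structure moves ΔI. The XOR construction h = x₁⊕x₂ gives
ΔI = +ln 2 (pure synergy).

Redundancy defaults to the kernel-difference score ‖K_z − K_x‖²_F between
RBF kernel matrices (median-heuristic bandwidth), zero iff the kernels
coincide. This is the score as used by the diagnostics this module mirrors;
it is *not* the standard Hilbert–Schmidt Independence Criterion, so the
standard biased centered HSIC is provided under `mode="hsic"` and labelled
as such.

## Training loop and reproducibility

Adam with cosine learning-rate decay; reference schedule 1e−4 → 1e−6,
batch 256, 100 epochs. Desk-scale (`TrainConfig.smoke`): 200 synthetic
conformers, 5 epochs, batch 32, queue 512, a 2-layer/hidden-64/8-head
encoder, and a faster schedule (2e−3 → 2e−4) appropriate for the ~30
optimization steps such a run contains; these are the problem sizes the test
suite and the acceptance script use. Runs are deterministic given (corpus,
config, seed) in single-threaded execution; checkpoints (npz arrays + JSON
manifest) round-trip bit-identically. NaN losses abort with a diagnostic
naming the offending batch. Every step logs per-scale losses, λ, and the
−L + log N bounds as JSON lines.

The linear-probe evaluation (`finetune`) fits ridge or logistic regression
on frozen concatenated scale embeddings over 5 random splits and reports the
mean with a 95 % t-interval, t₀.₀₂₅,ₙ₋₁·σ/√n — the standard form of the
t-interval (a variant dividing by n instead of √n circulates; we use √n).

## The synthetic test bed, and its limits

The generator produces ideal-geometry conformers — alkane chains
(C–C 1.54 Å, 109.47° backbone angles, torsions from {180°, ±60°}), planar
regular rings, and hetero-decorated scaffolds — whose every internal
coordinate is known by construction, making geometry recovery and
augmentation contracts exactly checkable. It deliberately omits: hydrogen
atoms (united-atom backbones), bond-length/angle vibration, ring pucker,
torsion correlations, electrostatics, and any energy model. Consequences:
passing tests establish the *mechanics* of the framework (symmetries,
normalization, bounds, recovery, specialization) on controlled geometry;
they do not establish chemical-accuracy claims on real conformer ensembles,
benchmark transferability, or anything about force-field-quality energetics.
The small discrete torsion alphabet also means distinct sampled molecules
can be identical conformers, which matters for probe evaluations (train/test
leakage of duplicates) and is why probe tests use diverse size ranges.

## Known limitations

* The multiplicative logit gate cannot *suppress* out-of-band pairs below
  the uniform level; a masking variant would change the attention semantics
  and is intentionally not the default.
* λ weights trained jointly by descent drift toward the scale with the
  smallest loss; with roughly balanced losses they stay near ⅓, and no
  claim is made that this schedule is optimal.
* The KSG estimator degrades in high dimension; diagnostics standardize and
  work on ≤96-dimensional embeddings at n in the hundreds, where bias is
  visible but directionally stable.
* Training is pure-numpy autodiff: transparent and finite-difference
  checkable, but orders of magnitude slower than GPU frameworks; it is
  intended for desk-scale studies, not corpus-scale pre-training.
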