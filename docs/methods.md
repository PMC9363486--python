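# Methods

## Model

The classifier is a two-layer capsule network with dynamic routing by
agreement, specialized to two class capsules: *normal* (index 0) and
*anomaly* (index 1).

**Primary capsules.** A convolutional preprocessing layer (default: 8
filters, 3×3, stride 1, ReLU; ELU selectable) feeds a bank of `O_P`
parallel convolutional layers of `N_f` filters each (default 5×5, stride
3). Primary capsule `i` is a (filter, spatial position) site; its vector is
that site's response across the `O_P` parallel layers, squashed:

    S(x) = (‖x‖² / (1 + ‖x‖²)) · x/‖x‖

so every capsule vector has norm < 1 and the norm is monotone in the raw
response. `S(0) = 0` by the continuity limit; the differentiable version
used inside the network smooths the division at zero with ε = 1e−12.

**Routing.** Each primary capsule `i` holds one routing logit per class
capsule `j`, initialized to zero, so first-iteration couplings are uniform
(`c_ij = 1/N_S`). Each of the (default 3) iterations computes
`c_i = softmax_j(logits_i)`, forms `s_j = Σ_i c_ij (W_ij u_i)` with the
learned transform slices `W_ij` (shape `O_S × O_P`), squashes to `v_j`, and
— on all but the last pass — adds the agreement `⟨W_ij u_i, v_j⟩` to the
logits. Couplings are exposed as a `(N_P, N_S, O_S)` tensor with the scalar
`c_ij` broadcast across the output dimension; the inequality scores are
scale-invariant, so summing over `O_S` (a factor `O_S · c_ij`) gives the
same values as per-dimension couplings would.

**Objective.** Class probabilities are a softmax over the class-capsule
norms `Ŷ_j = ‖v_j‖`. Training minimizes the margin loss

    L_k = T_k · relu(m⁺ − Ŷ_k)² + λ (1 − T_k) · relu(Ŷ_k − m⁻)²

summed over capsules (T_k = 1 for the true class), plus `α · MSE(X, X̂)`
for a two-layer MLP decoder reading the true-class capsule (argmax capsule
at inference). With anomaly masking on (default), anomalous examples
contribute no reconstruction term, so the decoder models normal data only.

## Anomaly scores

For each input the contribution vector of the anomaly capsule is
`M₁[i] = Σ_l c[i, 1, l]`. Scores:

| score | definition | declared polarity |
|-------|------------|----------|
| gini  | `Σ_i (2i − n − 1) M_(i) / (n Σ M_i)`, ascending sort | higher = anomalous |
| palma | `Q90(M)/Q40(M)`, linear-interpolation quantiles | higher = anomalous |
| plain | anomaly-class probability | higher = anomalous |
| A     | `Ŷ_normal − Ŷ_anomaly + MSE(X, X̂)` | higher = normal |
| N_pp  | `max_j Ŷ_j` | higher = normal |
| N_re  | `MSE(X, X̂)/‖X‖₂` | higher = anomalous |

Gini requires an ascending sort (the sorted-index form is order-dependent
otherwise) and rejects all-zero or negative input. Palma returns a flagged
sentinel (1e12) when `Q40 < 1e−12`; couplings are strictly positive softmax
outputs, so this can only fire on degenerate inputs. Both statistics are
scale-invariant, verified to 1e−10.

**Orientation.** Whether anomalous inputs *raise* or *lower* the coupling
inequality on the anomaly capsule is regime-dependent. With two class
capsules, routing is zero-sum across capsules: for a *normal* input, the
primaries that vote normal push their anomaly-capsule couplings toward 0,
creating an unboundedly unequal lower tail (Gini-visible); an *anomalous*
input instead raises the upper tail from the uniform baseline
(Palma-visible). At desk scale we observe near-perfect but *inverted*
Gini separation, and the sign differs between Gini and Palma and between
modalities. The harness therefore treats orientation as a fitted property
of each trained model: each score's sign is calibrated on the training
split (flip when training AUROC under the declared polarity is below 0.5)
before held-out evaluation. No test labels are used. The declared
polarities above remain the defaults when no calibration data is supplied.

## Baselines

**NL** — a Bernoulli-Bernoulli RBM trained with single-step contrastive
divergence, `δw = σ · E[(vh)_data − (vh)_recon]`, with σ = +1 on normal
and −1 on anomalous examples; within an epoch all positive updates precede
all negative ones. Scoring uses a deterministic mean-field
visible→hidden→visible pass so scores are reproducible (the sampling step
is used only during training, seeded).

**ABC** — a symmetric MLP autoencoder (default one hidden layer of 32,
sigmoid output) trained per example with
`y·MSE − (1 − y)·log(1 − e^(−MSE))` where y = 1 marks a *normal* example;
the log argument is clamped to [1e−8, 1], so a perfectly reconstructed
anomaly incurs a large finite penalty. Both baselines see flattened inputs
min-max scaled to [0, 1] and score by reconstruction error
(higher = anomalous).

## Experiment construction and evaluation

Two split procedures turn a labeled multi-class set into an
anomaly-detection problem. *Diverse outlier*: all examples of a focal
class are the normal set (label 0) and `A = round(fraction × focal count)`
examples sampled uniformly without replacement from the other classes are
the anomalies. *Diverse inlier*: the focal class is the anomaly set in
full, and `round(focal count / fraction)` normals (capped at availability)
are sampled from the rest. `fraction` is interpreted relative to the
normal-set size so the anomaly share of a split approximates the nominal
fraction. Each split is further partitioned 70/30 stratified by label;
models train on the 70%, every score is evaluated on the 30%.

AUROC is rank-based with midrank ties, average precision the step-wise
precision-recall sum (both via scikit-learn, cross-checked in the tests
against exhaustive pair-counting and threshold-sweep oracles on all label
vectors of length ≤ 8). Grids enumerate
(dataset × setup × fraction × focal class) cells — one trained model per
cell, per-cell seeds derived from a master seed via `SeedSequence` — and
results aggregate as mean ± std over focal classes. Cell failures are
collected and reported, never dropped.

## Sequence pairs

A gRNA-target pair is two 23-nt strings over {A, C, G, T}. Pairs are
one-hot encoded to a `(2, 4, 23)` tensor (channel 0 target, channel 1
gRNA; rows alphabetical A, C, G, T; ambiguity codes rejected with the
offending position). Pairs with more than 6 positional mismatches are
discarded — off-target cleavage is considered impossible beyond that — and
the filter keeps exactly the ≤ 6 boundary.

## Synthetic fixtures

**Images.** Each class is a fixed arrangement of 2–3 part motifs (bars,
corners, crosses, blobs on 5×5 stamps) at distinct anchors; distinct
classes share at most one motif, emulating the part-whole premise that a
rare class is built from parts largely absent from the common class.
Realism knobs, chosen once: position jitter ±2 px, per-motif intensity
gain U(0.6, 1.0), additive Gaussian pixel noise σ = 0.15, clipped to
[0, 1] — parts remain clearly visible while single-pixel evidence is
unreliable. The fixture does **not** emulate pose/scale variation,
occlusion, background clutter or class overlap beyond noise; at benchmark
sizes the two classes remain almost perfectly separable, so passing tests
show the scores work, not that they dominate a saturated classifier (see
Limitations).

**Pairs.** Random 23-mers with an NGG-style PAM tail. Off-targets carry
1–6 mismatches concentrated PAM-distal (protospacer positions 1–10);
normal pairs carry 1–6 uniformly placed mismatches and GC-biased target
composition, so the label is learnable from positional patterns and every
pair survives the 6-mismatch filter by construction.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| O_P / N_f / O_S | 8 / 8 / 16 | the classic capsule dimensions, filter bank scaled to 16×16 inputs |
| routing iterations | 3 | standard; more iterations sharpen polarization but rarely change ranking |
| m⁺ / m⁻ / λ | 0.9 / 0.1 / 0.5 | classic margin-loss settings |
| α (reconstruction) | 5e−4 | regularizer, keeps MSE term subdominant |
| optimizer | Adam, lr 3e−3, batch 32, 10 epochs | strong enough that routing actually polarizes; weaker schedules leave couplings near-uniform and inequality scores uninformative |
| Palma quantiles | linear interpolation | the common default; quantile dialects change small-n values |
| test fraction | 0.3 stratified | evaluation partition; the sources do not state one |

Training is deterministic given a seed (pure-numpy forward/backward);
bitwise reproducibility across machines additionally requires identical
BLAS builds. All randomness flows through explicit seeds
(`numpy.random.default_rng`).

The gradient machinery is a small reverse-mode autodiff engine over numpy
arrays (broadcast arithmetic, two-operand einsum, im2col convolutions,
reductions, pointwise nonlinearities), gradient-checked against central
finite differences in the test suite.

## Limitations

- At desk scale the supervised capsule classifier separates the synthetic
  fixtures almost perfectly (plain-probability AUROC ≈ 0.97–1.0), so the
  inequality scores — excellent in absolute terms (AUROC ≈ 0.89–0.99
  held-out) — cannot *exceed* a saturated comparator. The regime where
  coupling inequality outranks the plain probability is hard
  classification (complex natural images, real off-target data), which a
  small clean fixture intentionally does not reproduce.
- The Gini/Palma orientation must be calibrated per trained model; the
  fixed declared polarity is not reliable across regimes.
- Two class capsules only; multi-class anomaly setups, alternative routing
  schemes (EM, attention, spectral) and stacked classifiers on top of the
  inequality features are out of scope.
- The NL RBM width/epochs follow no published values; they are exposed in
  the API and chosen here to be comparable in effort to the other models.
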