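# Methods

## Model and sign conventions

A network is an ordered stack of layers `x_{l+1} = σ(W_{l+1,l} x_l + b_{l+1})`
with `σ ∈ {relu, identity, tanh}` and a softmax cross-entropy read-out. The
error carried by layer `l` is defined *down-gradient*, `e_L = −∂ℒ/∂x_L` at
the output and `e_l = σ′(z_l) ⊙ (backward map of e_{l+1})` below it, so all
updates are additive: `W ← (1−γ)W + η·mean_batch(e_{l+1} x_lᵀ)`. Note the
hidden errors are preactivation gradients (the σ′ gate belongs to the layer
that produced the activation); the finite-difference oracles in the test
suite differentiate with respect to preactivations accordingly. ReLU's
derivative at exactly 0 is taken as 0, which the exact-reduction tests rely
on. Errors and updates are *averaged* over the minibatch (not summed) so
learning rates are comparable across batch sizes. Biases receive no weight
decay and have no feedback analogue.

## Backward rules

| mode | backward map for layer l |
|---|---|
| `bp` | `Wᵀ e_{l+1}` (weight transport) |
| `fa` | `B_fa e_{l+1}`, fixed `B_fa` with entries N(0, 1/N_{l+1}) |
| `dfa` | `B_dfa e_L`, fixed `B_dfa` with entries N(0, 1/N_L) |
| `sf` | `sign(Wᵀ)·c_l · e_{l+1}`, rebuilt from the current W each pass |
| `kp` | product rule with `B = I`; R gets the transposed W update |
| `pfa` | `R (B e_{l+1})`, `B` i.i.d. N(0, 1/N̄), `R` plastic |
| `pfa_o` | as `pfa` with semi-orthogonal `B` (`BᵀB = I` exactly) |

The SF magnitude is one scalar per layer, `c_l = mean|W|`, recomputed every
backward pass: a parameter-free choice that keeps the feedback norm ratio
near 1. KP is not a separate code path — it is the product rule with an
identity `B`, which makes its feedback update (`ΔR = η x e_{l+1}ᵀ`) exactly
the transpose of the forward update, so one tested kernel serves both.

With a semi-orthogonal `B` and the matched initialization `R₀ = W₀ᵀBᵀ`
(`r_init="matched"`), the identity `Bᵀ ΔRᵀ = ΔW` makes `R B = Wᵀ` hold
after every step, so PFA-o reproduces BP's loss curve to machine precision
for an entire run — the executable form of the aligned-update argument.
With `lr_r = 0` and no R decay the product rule degenerates to FA whose
fixed feedback is the initial product `R₀B₀` (identical trajectories up to
float association order).

## Initialization and gain conventions

Forward weights use LeCun scaling (variance `1/N_in`), biases start at 0.
All *fixed* feedback matrices use the fan-based variance that gives the
backward map unit norm gain (`1/N_{l+1}` for FA, `1/N_L` for DFA,
`1/(N_{l+1}·h·w)` for conv FA kernels). The plastic `R` uses variance
`1/N_l` (conv: `1/(N_l·h·w)`): with `B` of variance `1/N̄` this gives the
composed path `R B` unit norm gain and an initial norm ratio of 1. An
earlier draft used `1/N̄`, which silently scales the backward gain by
`λ·N_l/N_{l+1}` per layer and stalls deep networks — a reminder that the
product pathway has *two* gains to control, not one.

## Sparse feedback

A Bernoulli(1−p) mask is drawn once per feedback matrix at initialization
and enforced after every update; masked entries are exactly zero for the
whole run. Two norm-preserving conventions accompany the mask:

- **Init rescale.** Surviving entries of every fixed feedback matrix (and
  of R's random init) are scaled by `1/√(1−p)`, so `E[BᵀB] = I` continues
  to hold for sparse `B`. Without this, masking silently multiplies the
  backward gain by `(1−p)` per factor — `(1−p)²` for the product rule —
  confounding the sparsity manipulation with a gain change.
- **Density-compensated plasticity.** The masked R update carries only
  `√(1−p)` of the dense update norm, so the plastic path's equilibrium
  norm gain decays to `√(1−p)` under a shared learning rate. The default
  feedback rate is therefore `lr_r = lr/√(1−p)` (an explicit `lr_r`
  overrides it). This is the same correction dropout applies to unit
  activations, and it restores the near-1 path norm ratio that is the
  product rule's stability property.

## Convolutional layers

Feature maps are `(batch, channel, h, w)`; kernels `(out, in, kh, kw)`.
Forward convolution is im2col-based cross-correlation; the backward rules
share one primitive, the transposed convolution (`conv_input_grad`), which
carries the 180° kernel flip implicitly. For the product rule the fixed
`B` is a 1×1 channel mixer applied pixelwise at the *upper* layer's
resolution — so `ē` has the same spatial size as `e_{l+1}` and the R
update is the standard kernel gradient — while the plastic `R` has the
forward kernel's spatial extent and carries all of its
stride/padding/dilation through the transposed-conv operator. The composed
effective kernel `K_eff[i] = Σ_k B[k,i] R[k]` is what the path-alignment
metric compares to `W`; using it as a fixed FA kernel reproduces the
two-factor error exactly, which the tests exploit as a composition oracle.
`groups ≠ 1` is not supported.

## Diagnostics

Weight/path alignment is `arccos` of the normalized inner product of the
vectorized forward transpose and the vectorized backward structure, in
degrees (0° = backprop-equivalent; a zero-norm operand raises rather than
returning 0, except inside the training loop's epoch logging, where it is
recorded as NaN). The norm ratio `‖backward‖_F/‖Wᵀ‖_F` uses the Frobenius
norm, consistent with the vectorization used for angles. DFA's per-layer
feedback is not shape-comparable with `Wᵀ`, so its diagnostics are NaN.
Metrics are recorded at epoch end.

## Synthetic tasks

Teacher tasks draw i.i.d. standard-Gaussian inputs (already standardized)
and label them by the argmax of a fixed random teacher network (linear for
`teacher_depth=1`, tanh hidden layers otherwise); zero teacher biases keep
classes near-balanced by symmetry, and `noise_rate` resamples that fraction
of labels uniformly. The conv generator labels small images with a random
conv → relu → global-average-pool → linear teacher. Everything is
bit-reproducible from the seed. These tasks emulate the *optimization*
structure of small image-classification benchmarks (separable-to-margin or
teacher-realizable targets, balanced classes) but not their input
statistics (sparsity, spatial correlations, manifold structure), so passing
results demonstrate correct credit-assignment behaviour, not benchmark
accuracy on real data. MNIST itself is supported through the IDX reader
and the CLI (`fetch-mnist` downloads; the library never touches the
network).

## Experiment problem sizes

The canned experiments (`pfanet.experiments`) run in minutes on one CPU:

- **Alignment protocol**: 784–512–512–10 ReLU (the benchmark architecture),
  expansion ratio 10, on a 10-class linear-teacher task with 6000 samples;
  15 epochs, batch 64, lr 0.2, two-phase decay 0.01 (5 epochs) → 5e-4.
  The large initial decay erases the random initializations so the
  update-driven alignment shows through — end-of-run angles land at
  ~18° (PFA), <6° (PFA-o), 70–83° (FA), ~27° (SF), with path norm ratios
  near 1.
- **Sparsity comparison**: 32–32–32→10-class depth-2 teacher task, 40
  epochs (to plateau), p = 0.9, 5 seeds. The narrow 32×10 top-layer
  feedback is the regime where sparse per-layer feedback strands ~1/3 of
  units with no error signal at all (`0.9¹⁰ ≈ 0.35`), while the expanded
  intermediate population keeps every unit connected with high
  probability — the redundancy argument for the product rule. The paper's
  sparsity study uses a two-hidden-layer protocol; deeper analogues were
  deliberately avoided because the `√(1−p)` plastic-gain loss compounds
  with depth.
- **Conv comparison**: 8×8 single-channel images, 1200 samples, 2 classes,
  4 epochs, expansion ratio 4.

## Numerical choices and degenerate inputs

Double precision throughout. Softmax is computed with max-shift
stabilization. Divergence (non-finite loss or update) raises a structured
error naming the step and the last epoch that completed finite. Exact
reductions are asserted bit-for-bit where the arithmetic is identical
(KP ≡ PFA with `B=I`) and to ≤1e-6 / machine-epsilon tolerances where only
association order differs. The Marchenko–Pastur support check uses a
finite-size slack of 0.1 at `N = 200` (edge fluctuations shrink like
`N^{-2/3}`, so the slack should be tightened for larger N). Semi-orthogonal
matrices come from QR of a Gaussian matrix with R's diagonal signs folded
in (Haar-distributed column space); `init_semi_orthogonal` rejects
`n_rows < n_cols`, where the defining property is unattainable.

## Known limitations

- No GPU path and no autodiff; everything is explicit numpy, sized for
  desk-scale experiments.
- Convolutions support stride/padding/dilation but not grouped channels;
  no pooling, batch norm, or residual blocks.
- SF, DFA and KP are dense-only (the conv backward rules cover bp/fa/pfa/
  pfa-o).
- Momentum is plain heavy-ball on W and R and is off by default; no
  adaptive optimizers or learning-rate schedules beyond the two-phase
  weight decay.
- The expansion ratio must be ≥ 1: a contracting intermediate population
  would reduce the rank of the transmitted errors, which is a different
  regime from the one studied here.
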