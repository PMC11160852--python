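# pfanet — credit assignment without weight symmetry

Backpropagation requires the backward pathway to use the transpose `Wᵀ` of
the forward weights — a synapse-level symmetry that biological circuits do
not exhibit. `pfanet` implements **product feedback alignment (PFA)**, a
learning rule in which the error reaching layer *l* travels through a
*factored* backward pathway: a fixed random matrix `B` (shape `N̄×N_{l+1}`)
projects the upper-layer error onto an expanded intermediate neuron
population, and a plastic matrix `R` (shape `N_l×N̄`) maps it back,

    ē_l = B e_{l+1},      e_l = σ′(z_l) ⊙ (R ē_l),
    ΔW = η e_{l+1} x_lᵀ,  ΔR = η x_l ē_lᵀ,   (both with weight decay)

so that the *product* `R B` comes to align with `Wᵀ` while no pair of
neurons ever carries reciprocal symmetric weights. The mechanism relies on
`BᵀB ≈ I`: exactly true for a semi-orthogonal `B` (the PFA-o variant), and
true in the large-expansion limit for i.i.d. `B` with entry variance
`1/N̄`, where the spectrum of `BᵀB` follows the Marchenko–Pastur law with
support `(1±√λ)²`, `λ = N_{l+1}/N̄`.

The package is aimed at researchers studying biologically plausible credit
assignment. It provides, in pure numpy:

- dense and convolutional forward/backward/update kernels for **seven
  rules**: `bp`, `fa` (feedback alignment), `dfa` (direct FA), `sf`
  (sign-concordant feedback), `kp` (Kolen–Pollack), `pfa`, `pfa_o`;
- the alignment diagnostics used to compare them (weight/path alignment
  angle, weight/path norm ratio);
- random-matrix analysis of the feedback product (`mp_support`,
  `mp_density`, `empirical_spectrum`, `path_alignment_vs_ratio`);
- sparse-feedback masking with norm-preserving conventions;
- a seeded training harness, synthetic teacher-network task generators, an
  MNIST IDX reader (no auto-download), a scikit-learn estimator
  (`FeedbackNetClassifier`), and a CLI (`pfanet`).

## Worked example

```python
from pfanet import FeedbackNetClassifier, gen_teacher_task

data = gen_teacher_task(input_dim=20, n_classes=2, n_samples=2000,
                        teacher_depth=1, seed=3)
for alg in ("bp", "pfa", "fa"):
    clf = FeedbackNetClassifier(algorithm=alg, hidden_layer_sizes=(32,),
                                max_epochs=15, learning_rate=0.1,
                                random_state=0)
    clf.fit(data.X_train, data.y_train)
    angle = clf.history_.metrics_frame().query("epoch == 15").angle_deg.mean()
    print(f"{alg:>4}: test accuracy {clf.score(data.X_test, data.y_test):.3f}, "
          f"final loss {clf.loss_curve_[-1]:.4f}, alignment {angle:.1f} deg")
```

prints

```
  bp: test accuracy 0.988, final loss 0.0455, alignment 0.0 deg
 pfa: test accuracy 0.988, final loss 0.0385, alignment 21.3 deg
  fa: test accuracy 0.984, final loss 0.0390, alignment 51.5 deg
```

All three rules solve this separable task; the alignment column is the
angle between `vec Wᵀ` and the vectorized backward pathway (`R B` for PFA,
the fixed `B` for FA; 0° means a backprop-equivalent pathway). PFA's
plastic product aligns far better than FA's fixed feedback — that is the
algorithm's point — without any weight transport.

From the shell, the same machinery is available as:

```
pfanet train --algorithm pfa --epochs 15 --out runs/pfa
pfanet spectrum --n 200 --ratios 1,2,5,10,50
pfanet angle-vs-ratio
pfanet sweep-sparsity --levels 0.0,0.5,0.9 --algorithms pfa,fa
pfanet train --dataset mnist --mnist-dir data/mnist   # after fetch-mnist
```

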