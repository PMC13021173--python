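# Methods

This note records the models, conventions and training recipes the
package implements, at the level of detail needed to reproduce or audit
its behavior. All randomness is routed through seeded
`numpy.random.Generator` instances; identical inputs + seeds give
identical outputs everywhere.

## 1. Sequence model and descriptors

Peptides are uppercase strings over the 20 canonical amino acids
(`ACDEFGHIKLMNPQRSTVWY`, fixed alphabetical order used for all
vectorizations). Labels, when present, index nine cancer types (0–8).

The physicochemical block per peptide is 430 numbers:

- **Amino-acid composition (20)** — residue fractions.
- **Dipeptide frequency (400)** — adjacent-pair frequencies, row-major
  over the alphabet; a length-1 peptide maps to zeros.
- **Global properties (10)** — length; monoisotopic molecular weight;
  net charge at pH 7; isoelectric point; mean Eisenberg hydrophobicity
  (GRAVY); hydrophobic moment; instability index; aromaticity; basic
  (K/R) fraction; aromatic–basic pair count (window 3).

**Net charge** follows the Henderson–Hasselbalch formulation: each basic
group (N-terminus, H, K, R) contributes `1/(1+10^(pH−pKa))`, each acidic
group (C-terminus, D, E, C, Y) contributes `−1/(1+10^(pKa−pH))`. The
default pKa set is N-term 8.0, C-term 3.1, D 3.65, E 4.25, C 8.3,
Y 10.07, H 6.0, K 10.5, R 12.5; it reproduces the reference charge
profile pinned in the acceptance tests to two decimals. The
**isoelectric point** is the unique root of the (monotone) charge curve,
found by bisection to |charge| < 1e-4; tests compare it against a
20000-point grid scan.

The **hydrophobic moment** is the normalized vector sum
`‖Σ h_k (cos kδ, sin kδ)‖ / L` on the Eisenberg consensus scale with
δ = 100° per residue (α-helix). The **instability index** is the
Guruprasad dipeptide-weight statistic `(10/L)·Σ DIWV`, using the
published weight table shipped with biopython; the implementation matches
`Bio.SeqUtils.ProtParam.ProteinAnalysis.instability_index` exactly.

## 2. Embedding, fusion, reduction

Each sequence receives a 1024-dim embedding. The default backend hashes
overlapping 3-mers (blake2b) into 4096 count buckets, projects with a
fixed-seed Gaussian matrix to 1024 and L2-normalizes — deterministic and
dependency-free. An optional ProtBERT adapter satisfies the same
contract when `transformers` and local weights are available.

Fusion concatenates [embedding (1024) | descriptors (430)] → 1454. The
reduction model standardizes per column (zero-variance columns get unit
scale) and applies exact full-SVD PCA to 200 components, with each
component's sign fixed so its largest-magnitude loading is positive.
Reductions are always fitted on training folds only.

## 3. MECS attention encoder

Reduced features are reshaped to grids (B, 8, 1, 25) and passed through
the multiscale embedding-compression block:

1. 1×1 convolution + GELU (global perception);
2. channel attention from average, max and lower-median spatial pooling,
   each through one shared Conv–ReLU–Conv pointwise MLP (reduction ratio
   4) and a sigmoid, summed — so each channel weight lies in (0, 3);
3. spatial attention: 5×5 depthwise convolution, then three depthwise
   asymmetric pairs (1×7·7×1, 1×11·11×1, 1×21·21×1), summed;
4. fusion: pointwise convolution of the spatial map, multiplied with the
   channel-weighted grid, then a final pointwise integration.

In the classifier the MECS output enters through a learnable scalar gate
initialized at zero: `refined = x + gate · MECS(x)`. See §7.

## 4. Noise-conditioned classifier

Architecture: MECS-refined 200-dim features → linear projection to 64;
conditioning `x_cond = x_proj + c_proj + TimeEmbed(t)` where `c_proj` is
a learned embedding per class plus a dedicated null-condition embedding
and `TimeEmbed` is sinusoidal (half sines, half cosines at geometric
frequencies) behind a zero-initialized linear projection; a residual
two-layer GELU backbone plus K = 3 parallel Conv1d branches (kernels 3,
5, 7) fused by learnable scalar weights, `y = F(x) + Σ wᵢGᵢ(x)`; softmax
head over 9 classes.

Training, per stratified fold (default 5): fit the standardize+PCA
reduction on the training split; SMOTE the training split to exact class
balance (synthetic point = `x_i + u(x_nn − x_i)`, u ~ U(0,1), x_nn among
the k = 5 same-class nearest neighbors; originals preserved verbatim);
draw `t ~ U(0,1)` per sample and drop the condition to null with
probability 0.2; minimize class-weighted cross-entropy
(inverse-frequency weights normalized to mean 1) with Adam (lr 1e-3,
decoupled weight decay 1e-2); early-stop on validation macro-F1
(patience 10). The best-validation fold's parameters are retained.
Inference uses the null condition and t = 0, so predictions are
deterministic.

Metrics: accuracy, macro precision/recall/F1
(`sklearn.precision_recall_fscore_support`), one-vs-rest AUC per class
via the Mann–Whitney rank statistic (midranks on ties) averaged over
classes present, and a truth-by-row confusion matrix.

## 5. Conditional diffusion generator

The generator models the standardized 420-dim invertible descriptor
subspace (composition + dipeptide) under the forward process
`x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε` with a linear β schedule (1e-4 → 0.02,
T = 1000), training an ε-prediction denoiser by MSE with Adam.

The denoiser reshapes inputs to (B, 4, 105) maps and couples two fusion
blocks. **BFM**: parallel Conv1d at receptive fields {3, 7, 15} over the
conditioned input, summed, plus a residual. **TFAM**: both temporal
states (conditioned input T₁ and BFM output T₂) pass multiscale
Conv+ReLU sums (kernels {3, 5, 7}); channel weights come from a
two-branch softmax over a 4-channel pooled descriptor
[mean(T̂₁), max(T̂₁), mean(T̂₂), max(T̂₂)], spatial weights from a
two-branch softmax of two Conv2d maps of the channel-pooled descriptor;
the residual fusion coefficients are `β_i = 1 + α_c(i) + α_s(i)`, so
β₁ + β₂ = 4 identically (a tested invariant).

Time and label conditioning enter as a feature-wise affine (FiLM-style)
modulation of the input map — zero-initialized scale/shift heads off the
sinusoidal time embedding, label embedding added to the scale — plus a
learned scalar skip on the noisy input. Purely additive conditioning
cannot express the time-scaled component of ε and made trained samplers
diverge; the affine form fixes this (see the repository's test
`test_gaussian_mean_recovery`).

Sampling is a deterministic first-order ODE solver (a DPM-Solver-1
update `x ← (α_s/α_t)x − σ_s(e^h − 1)ε̂` on uniformly spaced log-SNR
knots, default 25 steps) with a final exact denoise-to-data step; an
oracle denoiser for a point mass returns that point to numerical
precision, and the 25-step path matches the 1000-step path to 1e-8.
With trained (imperfect) denoisers the implied data prediction is
clipped to ±3 in standardized space (dynamic thresholding) to prevent
trajectory amplification; the raw sampler leaves this off by default.

**Decoding**: each sampled latent is un-standardized; the dipeptide
block (negatives clamped, +1e-3 smoothing, rows renormalized) becomes a
first-order Markov transition matrix and the composition block the
initial distribution; lengths are drawn uniformly from [8, 50] and the
chain is sampled. Decoding is deterministic given the seed.

## 6. Screening

**Novelty** — Smith–Waterman local alignment with affine gaps (Gotoh
recurrences; a gap of length g costs open + g·extend, defaults 11/1)
under BLOSUM62, with deterministic traceback tie-breaking (diagonal >
gap-in-b > gap-in-a). Scores are verified in tests against both an
independent recursive oracle and `Bio.Align.PairwiseAligner`. Each
candidate reports its best reference hit plus a gapless full-length
identity; ≥ 90% flags a near-duplicate (boundary inclusive).

**Motifs** — basic (K/R) and aromatic (W/F/Y) counts with per-residue
breakdowns; aromatic–basic proximity within 3 positions graded
absent/present/strong (strong = ≥ 2 pairs); the amphipathic moment is
the maximum μH over 11-residue windows. Helical wheels place residue k
at (100°·k) mod 360 with residue-class and hydrophobicity annotations.

## 7. Problem sizes, initialization and known limitations

- Default desk scales (hidden width 64, 4-channel denoiser, 5 folds,
  epochs ≤ 200 with early stopping) are chosen for single-CPU runtimes:
  classifier training on 540 peptides ≈ 20 s, 1500 diffusion steps ≈ 7 s.
- All residual refinements are zero-initialized (MECS gate, second
  backbone layer, branch weights wᵢ, time projections, FiLM heads): the
  untrained networks start at their identity/linear paths, which both
  stabilizes diffusion training and closes the generalization gap on
  small datasets (an unregularized random MECS path cost ~0.1 macro-F1
  versus a linear probe on identical features).
- The synthetic datasets imitate compositional class structure only.
  Performance numbers on them certify the machinery, not biological
  discrimination of real anticancer peptides.
- The generator models descriptor space, not sequences directly; decoded
  peptides reflect first-order composition/transition statistics of the
  sampled descriptors and carry no positional grammar beyond that.
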