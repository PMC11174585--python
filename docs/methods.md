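# Methods

## Model

### Frequency-domain graph convolution (F-GCN layer)

A feature map is a real tensor over (channels C, frames T, joints V).  One
layer performs four steps:

1. **Spatial aggregation.**  For each joint i,
   `x'_i = μ( (1/d_i) Σ_{j ∈ N(i) ∪ {i}} W_E(ij) · x_j )`, applied per
   channel and frame; μ is LeakyReLU (slope 0.01).  Every joint carries a
   self-loop so its own feature always contributes and no degree is zero;
   `d_i` counts the self-loop.  `W_E` holds one learnable weight per bone
   edge followed by one per self-loop (length |edges| + V), so the
   self-loop weights live in the same vector as the bone weights.
2. **Forward transform.**  (C, V) is flattened into a spatial axis S = C·V
   and an orthonormal 2D DFT is taken over (space, time).  Because the
   input is real, only F = ⌊T/2⌋+1 temporal bins are stored; the negative
   half is implied by conjugate symmetry.  (For even T this includes the
   Nyquist bin; the real-transform convention ⌊T/2⌋+1 covers even and odd
   T uniformly.)
3. **Spectral weighting.**  Each coefficient at (s, t) is scaled by the
   real factor `a[s]·b[t]` with
   `a[s] = θ( mean(θ(W_E)) · W_A[s] )` and `b[t] = θ(W_F[t])`, θ again
   LeakyReLU.  The spatial factor is then *symmetrized* across mirrored
   bins, `a[s] ← (a[s] + a[(S−s) mod S])/2`.  Rationale: a real separable
   mask that is conjugate-symmetric in both axes makes the whole filter a
   real symmetric linear operator, so (i) the inverse transform is exactly
   real — no imaginary residue to discard, (ii) phases are untouched, which
   yields circular time-shift equivariance, and (iii) the backward pass for
   the input is the operator itself (self-adjointness), which keeps the
   custom gradient simple and exact.  The temporal factor is symmetric by
   construction of the real FFT.  The edge-weight mean entering `a` ties
   the spatial mask to the learned graph weighting with dimensionally
   consistent shapes (a sum over edges cannot index spatial bins).
4. **Inverse transform** back to (C, T, V).

All mask and edge parameters initialize to 1, so an untrained layer is a
near-identity (aggregation aside); this stabilizes the first epochs.  Each
network block appends a pointwise channel-mixing linear map, initialized to
the identity so the block's at-initialization behaviour is unchanged; the
pathway weight of the per-pathway forward is read as including this
pointwise map.

### Pyramid and fusion

Three pathways share the joint axis but see different connectivity: the
pathway's partition masks bone edges to pairs inside one subset (global =
all bones; half = bones within upper/lower body; limb = bones within each
arm, leg and the torso).  Keeping all V joints in every pathway (a) makes
the partition invariant "every scale covers every joint" structural, and
(b) reduces coarse→fine feature alignment to the identity gather.  At depth
i, pathway ph ≥ 1 receives `concat( U·f(ph, i−1), W·f(ph−1, i) )` projected
back to its own width; the projection initializes to pass-through on the
fine block and zero on the coarse block.  Fusion is coarse→fine only.
Capacity decreases with granularity (default widths 64/48/32; the desk
benchmark uses 16/12/8), mirroring the heavier global / lighter limb
analysis.  The head mean-pools each pathway's final feature over frames and
joints, concatenates, and applies one linear map — the minimal standard
choice, isolated so alternatives are pluggable.

Ablation variants reuse the same code path: `fgcn_only` keeps the global
pathway (a plain stacked F-GCN classifier); `pgcn_only` keeps the pyramid
but creates no spectral masks, reducing each block to spatial aggregation.

### TCN baseline

The comparison baseline replaces the spectral steps by a fixed forward
window: `y_i(t) = Σ_{j ∈ N(i) ∪ {i}} Σ_{τ < s_d} W(·, τ) · x_j(t+τ)` with
zero padding at the sequence end (boundary handling is unstated in the
fixed-window formulation; zero padding is the plain choice).  The baseline
classifier mirrors the `fgcn_only` topology (same widths, depth, head) with
window s_d = 9 frames, so the comparison isolates the temporal mechanism.

## Autodiff

No tensor/autodiff framework is available in the supported environment, so
the package ships a small tape-based reverse-mode engine over numpy
(float32 by default for throughput; float64 on request, used by all
gradient checks).  Custom vector-Jacobian products cover channel mixing,
joint mixing, the FFT filter (self-adjoint, see above; mask gradients use
the doubling weights 2 − [t ∈ {0, Nyquist}] to account for the stored
half-spectrum), the temporal window convolution and the label-smoothed
cross-entropy.  Internally the time axis is kept last, (N, C, V, T), so
the spatial flattening for the FFT is a free reshape and joint mixing is a
single BLAS matmul.

## Synthetic data

The generator is phenomenological: a static rest pose (25-joint Kinect or
17-joint COCO layout, metres) plus sinusoids.  Legs swing along the forward
axis at the step frequency with left/right phases 0/π, arms counter-swing
their ipsilateral leg, per-joint amplitudes grow distally (`swing_weight`).
The left side's amplitudes are multiplied by the asymmetry ratio ∈ (0, 1].
The instantaneous cadence is modulated sinusoidally over the sequence by
the `speed_drift` fraction; step lift raises leg joints once per step;
lateral sway oscillates at the stride (half-step) frequency; tremor adds a
high-frequency sinusoid on the limbs; trunk lean shifts joints forward in
proportion to height.  Pose-estimation noise is i.i.d. Gaussian jitter plus
per-joint-per-frame dropout filled by holding the last observed position
(tracker-like; zero-fill selectable).  Cadence and tremor must lie below
the Nyquist frequency of the configured frame rate.

What this emulates: class-specific spectral signatures, amplitude
asymmetries, speed variability, and estimator noise — the features the
classifier exploits.  What it does not: ground-reaction physics, joint
angle limits, inter-subject anthropometric variation, view-dependent
projection, or temporal correlations of real tracker failures.  Passing
tests therefore demonstrate that the architecture learns the intended
invariances on data with that structure, not clinical performance.

The nine shipped phenotype recipes (normal, steppage, wadding, ataxic,
scissors, festinating, hemiplegic, chorea, antalgic) encode textbook
phenomenology — festinating fast/shuffling/leaning, hemiplegic strongly
asymmetric (ratio 0.45), ataxic irregular (25% speed drift), chorea with a
4.5 Hz tremor — and are illustrative, not clinically validated.

## Training protocol and desk scaling

`TrainConfig` defaults follow the full-scale protocol: SGD (momentum 0.9 —
the momentum value is this package's choice), learning rate 1e-4, batch 64
→ desk default 16, stratified 8:1:1 train/validation/test split, label
smoothing ε = 0.1 (ε unspecified upstream; 0.1 is the common default),
constant learning rate (only an initial rate is specified), model selection
by best validation accuracy with ties to the earliest epoch.  Splits are
deterministic for a seed: per class, items are shuffled and dealt so global
split sizes track N·(0.8, 0.1, 0.1) exactly (largest-deficit assignment of
the per-class remainders).

The shipped benchmark is four phenotypes × 100 sequences of 120 frames at
30 fps on the 25-joint layout with mild noise (jitter sd 0.01 m, dropout
2%).  Its training configuration uses learning rate 0.1 with momentum 0.9
for 20 epochs at batch 16: a rate of 1e-4 suits a 200-epoch GPU schedule on
~1600 real videos, whereas this float32 numpy model sees 320 training
sequences for 20 epochs, and the identity-initialized masks need a step
size large enough to differentiate within that budget.  The speed-
robustness experiment trains its two single-pathway arms (frequency model
and TCN baseline) with learning rate 0.05 for 30 epochs — half the pyramid
rate, because those smaller models on the smaller 50-per-class sample are
unstable at 0.1, and the architecture comparison is only meaningful when
both arms fit the training data; the protocol is identical for both arms.  Problem sizes in
the tests and the acceptance script (100/class for learning and ablation,
50/class with a 25/class ±20% cadence-shifted probe set for the robustness
comparison, 3 seeds where averaging is needed) are chosen so the full suite
runs on one CPU at desk scale.  Accuracy is reported both micro
(sample-weighted) and macro (unweighted mean of per-class one-vs-rest
accuracies (TP+TN)/N) because the two genuinely differ and upstream
"average accuracy" conventions are ambiguous; all reported numbers are
test-split values.

## Numerical choices and degenerate inputs

* Orthonormal FFT scaling throughout; Parseval holds to ~1e-15 and the
  round trip to ~1e-15 in float64 (asserted at 1e-10/1e-6).
* Normalization preprocessing (on by default in training): center each
  frame on the pelvis joint(s), scale each sequence by its mean torso
  length; a torso length below 1e-9 leaves the sequence unscaled.
* Self-loops are implicit: an explicit (i, i) pair in an edge list is
  rejected, as are duplicate and out-of-range edges.
* A model is bound to a fixed frame count T (the temporal mask length is
  ⌊T/2⌋+1); variable-length input should be cropped/resampled first.
* Degenerate guards: empty joint subsets, single-class training sets,
  ε ≥ 1, cadence at/above Nyquist, windows longer than the sequence and
  split ratios that empty a split all raise validation errors.

## Known limitations

* The spatial-axis FFT treats the flattened channel×joint axis as
  periodic; its "frequencies" have no anatomical meaning, and the learned
  spatial mask is best read as a data-driven reweighting of that basis.
  Symmetrized masks halve the effective spatial-mask dof.
* The engine is single-threaded numpy; it is sized for the desk-scale
  experiments, not for GPU-scale datasets.
* Mean pooling over frames and joints makes class evidence enter as a
  small shift on a large common-mode embedding, so very short sequences
  and subtle phenotype pairs train slowly (the examples use strongly
  contrasted pairs for quick demonstrations).
* Fine→coarse feedback between pathways and per-pathway temporal
  resampling are deliberately not implemented.
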