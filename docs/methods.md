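# Methods

## The generative model

`dpcnet` implements a hierarchical spatiotemporal generative model of
grayscale image sequences.  At the lower level, each vectorized frame
`I_t ∈ R^M` is generated from a sparse latent state `r_t ∈ R^N` through a
dictionary of spatial filters `U` (columns are filters):

    I_t | r_t ~ N(U r_t, σ² I)

The temporal dynamics of `r_t` are not fixed: a higher-level state
`r_h ∈ R^{N_h}` is mapped by a small hypernetwork `H_θ` (a multi-layer
perceptron with tanh hidden units and a linear output) to `K` modulation
weights `w`, which mix a learned bank of transition matrices `{V_k}` into
the effective dynamics:

    w = H_θ(r_h),   V = Σ_k w_k V_k,
    r_t | r_{t-1}, r_h ~ N(ReLU(V r_{t-1}), σ_r² I)

with a standard-normal prior on `r_h`.  Because `r_h` selects the
*dynamics* of a whole sequence rather than its per-step content, the
higher level is pushed toward representations that are stable over the
timescale at which the dynamics are stable — the source of every
emergent phenomenon the package reproduces.

There is no nonnegativity constraint on the latent estimates; the ReLU
appears only inside the transition mean, and its subgradient at 0 is
taken to be 0.

## Inference

Filtering maintains a single MAP point estimate per step (a Dirac
approximation of the filtering posterior).  At step `t` the loss

    L_t = ‖I_t − U r_t‖²/(2σ²) + ‖r_t − r̄_t‖²/(2σ_r²)
          + λ‖r_t‖₁ + λ_h‖r_h‖²,      r̄_t = ReLU(V(r_h) r̂_{t-1})

is minimized jointly over `(r_t, r_h)` by proximal gradient descent:
`r_t` takes a gradient step on the smooth terms followed by
soft-thresholding (exact sparsity, stable at zero), `r_h` a plain
gradient step through the hypernetwork; both are warm-started (`r_t` at
the prediction `r̄_t`, `r_h` carried from the previous step).  If a
candidate update increases the loss, the step sizes are halved (up to 12
times), and a still-increasing update is rejected — the recorded
inner-loop loss is therefore non-increasing.  The first step uses the
reduced loss `‖I_0 − U r_0‖²/(2σ²) + λ‖r_0‖₁` starting from the zero
vector, and the first prediction is defined as the zero vector.
An alternating (r-then-r_h) schedule is available; the default is the
simultaneous one.

Everything is vectorized over a batch of equal-length sequences, which
is what keeps the trained-network experiments tractable on one CPU.

Defaults: `lr_r = 0.05`, `lr_rh = 0.01` for generic use; the experiment
protocols use `lr_r = 0.1`, `lr_rh = 0.05`, 100 iterations, tolerance
`1e-5` on the max-norm change (25 iterations and `1e-4` during training,
where the warm starts carry most of the work).

All gradients — including backpropagation through the hypernetwork for
both inference and learning — are computed analytically and are verified
against central finite differences in the test suite.

## Learning

Training alternates filtering a minibatch with the current parameters
and one Adam step on `U`, `{V_k}`, `θ` using the gradient of the
filtering loss summed across time and averaged across sequences, with
the MAP latents held fixed.  Columns of `U` are renormalized to unit L2
after each update to remove the sparse-coding scale degeneracy (the L1
penalty would otherwise be defeated by growing the filters).  Defaults:
minibatch 64, Adam at `5e-3`.

Two initialization details matter:

* The hypernetwork's output bias starts at `1/K`, so the modulated
  transition matrix at `r_h = 0` is the mean of the bank.  With a zero
  bias the ReLU in the transition mean blocks every gradient at the
  start (a dead network).
* Random transition banks are drawn as `c·I` plus spectral-radius-
  normalized noise.  A nonzero identity component (`c = 0.7` with noise
  radius 0.5 in the teacher protocols) produces temporally smooth
  sequences whose activity survives the transition ReLU; purely random
  stable matrices decay to silence within a few steps.

Noise/penalty weights are exposed per model.  The package defaults —
`σ² = 0.5`, `σ_r² = 0.25`, `λ = 0.02`, `λ_h = 0.005` — weight the
temporal prediction error strongly and the higher-level prior weakly.
This regime makes the higher level *functionally* carry the dynamics:
with a weak temporal term the network can reach a similar training loss
while treating `r_h` as a nuisance variable, and the motion-dependent
phenomena (flash-lag displacements, postdiction) disappear even though
direction can still be decoded from `r_h`.

## Synthetic stimuli

The generators emulate the statistical structure of the stimuli the
model family is studied with; no external media are used.

* **Moving sprites** (the handwritten-digit stand-in): one of eight
  programmatically drawn glyphs (bars, cross, ring, blob, L/T shapes,
  diagonal) translating at fixed speed in one of the four cardinal
  directions inside an 18×18 frame, 10 frames per sequence, with
  uniform random start positions and straight (reversing) bounces at
  the boundary.  Direction changes on the frame where the next step
  would cross the boundary (reflect-before-exit), so sprite mass is
  conserved exactly.  Labels (initial and per-frame direction, sprite
  identity, bounce frames) are exact by construction.  No whitening.
* **Bouncing datasets** for the three-level study: 20-frame sequences
  with either "straight" (left↔right, up↔down) or "clockwise"
  (left→up→right→down→left) boundary rules; at the study's frame size
  (16) and speed (1) every sequence contains at least two bounces.
* **White noise**: i.i.d. `N(0, 0.0075)` pixels, the stimulus-free
  control for the timescale analysis.
* **Drifting surrogates** for whitened natural patches: band-pass noise
  textures translating with per-sequence constant velocity (continuous
  direction, subpixel Fourier shifts), passed through the whitening
  pipeline.

What these stimuli do *not* emulate: the full spatial statistics of
natural video (occlusions, multi-object scenes, scale changes) and the
shape variability of real handwritten digits.  Passing tests therefore
show that the algorithms produce the claimed structure under the stated
dynamics, not that the learned filters match cortical data
quantitatively.

Whitening applies the frequency-domain amplitude filter
`|f|·exp(−(f/f₀)⁴)` per frame (`f₀` = 0.8 of Nyquist) — removing DC and
flattening a 1/f amplitude spectrum — followed by a first-order temporal
decorrelation `y_t = x_t − 0.8·x_{t-1}` (`y_0 = x_0`).  Both stages are
linear.

## Experiment protocols and scales

All protocols run on one CPU; sizes were chosen as the smallest at which
the qualitative signatures are stable across seeds.

**Self-consistency (teacher–student).**  A random smooth-dynamics
teacher (`M=16, N=8, N_h=2, K=2`) generates low-noise sequences.
Filtering them with the true parameters recovers the mixing weights `w`
(median cosine similarity > 0.9 after the within-sequence adaptation
transient).  A student trained from scratch on 400 teacher sequences
(100 epochs at Adam rate `3e-3`; at higher rates late training can
destabilize on some teachers) reaches held-out one-step image-prediction
R² > 0.8 on steps past the two-step adaptation transient, during which
prediction errors are expected to be large.

**Sprite study.**  The flagship network (`N=64, N_h=16, K=5`, hidden
width 64) trains on 2,000 sprite sequences for 8 epochs.  Timescales:
population-averaged per-neuron autocorrelation (per-trial mean/SD
normalization so ρ(0)=1; zero-variance series excluded) over lags 0–6,
fitted with `a·exp(−k/τ) + b` (multi-start nonlinear least squares).
The variance in the normalization is taken as the squared standard
deviation so that the lag-0 coefficient is exactly 1.  Decoding:
RBF-kernel SVM, stratified 5-fold, chance = per-fold majority-label
fraction.  Decoding features are the responses averaged over the early
window t=1..3 — after first-step adaptation, before most bounces — so
that direction information cannot enter through accumulated position
(start position is independent of direction); with whole-sequence means
the lower level decodes direction through position and the between-level
margin collapses.

**Flash-lag.**  Five-step constant-motion horizontal windows are
extracted from held-out sprite sequences.  The higher-level state is
either inferred from the first three steps or reset to zero; the probe
frame continues, stops, reverses, or terminates the motion (the flash is
the no-history, terminated case with the object shown only on the last
pre-probe step).  The percept is `U·ReLU(V̄ r̂_2)` with `V̄` built from
the post-correction `r_h`, its location the positive-rectified center of
mass, and displacements are signed along the original trajectory.  The
latency sweep filters the pre-probe steps at analysis settings and runs
the probe-step correction for a fixed 30-iteration window (the model's
"perceptual processing" axis), reading out the percept at stated
fractions of those iterations against the physical location at the step
before the probe.

**Recall.**  The memory study runs on a dedicated network with a fixed
retinotopic front end (100 unit-norm Gaussian-blob filters on a jittered
grid; only the dynamics are learned, at `σ_r² = 0.1`, `λ = 0.03`) and a
small-sprite corpus (5-px glyphs).  Both choices are geometric
necessities for the RF-distance analysis: a learned undercomplete
dictionary turns global, putting every RF centroid at the frame center,
and an 8-px sprite is as wide as a five-step trajectory, so no
sequential RF traversal could exist.  Three five-step constant-motion
episodes are each bound into a fresh associative memory
(`P = N + N_h`, `λ_m = 0.1`, `η_G = 0.05`, five Hebbian repetitions;
the DPC weights stay frozen).  Cue-triggered recall infers the memory
vector from the cue's sparse code with the higher-level block masked
out, retrieves `r_h` as the corresponding top-down prediction, and rolls
the frozen network forward (10 steps for the cross-correlation series).
The "before conditioning" control uses the fresh memory (synapses at
scale 1e-3, near-null recall).  Following the conditioning experiments
this emulates, only neurons with RFs within 3 px of the trajectory row
are analyzed.  The sequential-firing signature is measured on the
"after minus before" difference correlograms: pairs are binned by RF
distance, the lag of each bin's mean difference curve's peak is taken
(binning suppresses single-pair integer-lag quantization noise), and
the slope of peak lag against bin distance is reported, signed along
the episode's motion direction.

**Three-level study.**  Mixed straight/clockwise bouncing corpora
(16×16 frames, 5-px sprites, speed 1, T=24, at least two bounces per
sequence).  The two-level base (retinotopic front end, as in the memory
study) is trained on the mixture;
the gate threshold ρ is the 0.75 quantile of first-level prediction
errors on steps past the adaptation transient (t ≥ 3); one second-level
transition matrix per regime is pretrained on the gated loss; the third
level's hypernetwork is then trained on the mixture.  When the gate is
off, the second level's prediction target is its previous state
(identity hold), and the Gaussian prior penalty is applied to the third
level only.  Bounce type is decoded from the final-step modulation
weights (the current dynamics after the bounces); direction from the
pre-first-bounce window, where the two regimes are indistinguishable by
construction.  Time-averaged post-bounce weights are *not* used for the
bounce-type readout: they separate the regimes trivially through the
direction distribution (straight sequences stay on one axis, clockwise
ones visit all four), which measures the stimulus, not the abstraction.

## Numerical choices

* ReLU subgradient at 0: 0.  L1 handled by proximal soft-thresholding
  (subgradient with sign(0)=0 as fallback).
* Backtracking: step sizes halve on a loss increase, at most 12 times;
  a still-failing update is rejected.  Convergence: max-norm change
  below `tol`.
* Exponential-decay fits: multi-start over τ₀ ∈ {0.5, 1, 2, 5, 10},
  best residual kept; an amplitude near zero flags τ as unreliable; a
  total fit failure returns a flag rather than raising.
* Autocorrelation excludes zero-variance neuron/trial series (count
  reported) and uses an unbiased `1/(T−k)` lag normalization.
* Degenerate percepts (no positive pixel) yield NaN locations with a
  validity flag rather than an exception inside batch experiments.
* Memory inference uses a fixed `1/L` step (L = Lipschitz constant of
  the quadratic gradient), so it converges to the ridge solution; the
  equivalence is oracle-tested.

## Known limitations

* Desk-scale training leaves one-step image predictions blurry
  (held-out R² ≈ 0.5 on sprites).  Phenomena read out through the
  center of mass (flash-lag, postdiction) are robust to this blur;
  pixel-sharp novelty detection is not.  In particular, the three-level
  gate — a threshold on the first-level prediction error — does not
  separate bounce frames from ordinary frames at these scales: the
  blurred, hedging predictions spread the bounce surprise over the
  wall-approach steps, and wall position alone predicts that *a* bounce
  will occur, so the first level partially absorbs the event.  The gated
  machinery is implemented and verified structurally (the reduction to
  the two-level filter is exact, thresholds and masked losses are
  unit-tested), and the timescale hierarchy of the three levels emerges,
  but the regime abstraction at the third level requires a sharper base
  model than these scales deliver.
* The timescale hierarchy is measured over 10–20-step sequences, so the
  fitted τ values are comparable only within an experiment, not with
  values measured on much longer recordings.
* The sweep over inner-loop iterations treats gradient-descent
  iterations as a latency axis; only the ordinal structure
  (early-predictive, late-postdictive, smooth flip) is meaningful, not
  the absolute iteration counts.
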