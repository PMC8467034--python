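# Methods

## Forward model

The electromagnetic effect of blood flow is quasi-static: blood with
conductivity σ moving at axial velocity v (out of the imaging plane,
+z) through a uniform static field B along +x experiences a motional
EMF v×B along +y, and the induced potential u obeys the generalized
Poisson equation ∇·(σ∇u) = ∇·(σ(v×B)) on the heterogeneous neck
cross-section. The outer boundary (skin–air) and internal air-filled
lumina (trachea, esophagus) are insulating; the reference electrode e0
pins the gauge, u(e0) = 0.

Discretization is a cell-centered 5-point finite-difference scheme with
harmonic averaging of σ on cell faces, which handles the strong
conductivity contrasts (blood 1.12 S/m against spine 0.001 S/m and
insulating lumina) conservatively: a face touching a σ = 0 cell carries
exactly zero conductance, so insulating inclusions become internal
Neumann boundaries without special-casing. The operator is symmetric
positive semi-definite; grounding is imposed by pinning the e0 row and
column (symmetry-preserving). Systems are solved by sparse LU; because
the operator depends only on the conductivity map, one factorization
serves every right-hand side — velocity sources, field strengths and
reciprocal injections alike. Correctness is pinned by a
manufactured-solution test (u* = cos πx cos πy on the unit square,
observed order ≈ 2.0) and by discrete Kirchhoff balances.

Electrode model: point electrodes at the outermost skin cell along 12
equally spaced angular rays (complete-electrode contact impedance is out
of scope). Voltages are U_k = u(e_k) − u(e0), k = 1…11.

### Weight matrix

Row k of W is obtained from the reciprocal field of electrode k: unit
current injected at e_k and returned through the grounded e0, J_A =
−σ∇u_A evaluated at cell centers from the same harmonic face fluxes the
operator uses. The weight of cell i is the z-component of the reciprocal
Lorentz force times the cell area, W[k,i] = (J_A × B)_z S_i. Using the
face fluxes of the discrete operator itself makes W the exact discrete
adjoint of the forward map: on a matched grid, W v reproduces the PDE
electrode voltages to rounding for any velocity field supported on the
reconstruction window (the acceptance test asserts ≤ 5%). The sign
convention is fixed by this consistency check rather than by orientation
bookkeeping.

The measurement data are deliberately *not* generated through W: sample
voltages come from the full heterogeneous PDE on the stenosed phantom,
while W comes from the stenosis-free phantom at 0.10 T. This built-in
model mismatch is what keeps the inverse problem honest.

## Phantom

The neck is parametric: a 120×100 mm ellipse with a 2 mm skin and 4 mm
fat annulus, muscle background, and disc-shaped organs — cervical spine
(r 13 mm, posterior), trachea (r 8 mm, anterior, insulating), esophagus
(r 5 mm, insulating), two glands (r 6 mm), carotid artery (r 4 mm) and
jugular vein (r 5 mm) placed anterolaterally. Conductivities (S/m):
skin 0.005, fat 0.1, muscle 0.2, esophagus 0, cervical spine 0.001,
glands 0.6, trachea 0, artery 1.12, vein 1.12; all overridable. The
combined blood area is ≈ 1.5% of the cross-section, comfortably below
the 10% bound that motivates local (windowed) imaging. The
reconstruction window is a square cell window centered on the vessels:
51×51 (n = 2601) at full scale, 21×21 and 11×11 for the stock scaled
grids. A real neck is not elliptical and organs are not discs; the
phantom reproduces the *structure* of the problem (layered conductivity,
small off-center vessels, insulating inclusions), not any patient's
anatomy.

### Flow model

The artery carries a pulsatile waveform

    w(t) = v_peak · max(0, a0 + a1 sin(2πt/T) + a2 sin(4πt/T + φ)) / M,

with defaults (a0, a1, a2, φ) = (0.45, 0.45, 0.3, 0.3), period T =
0.85 s, and M normalizing the clipped pulse to peak v_peak = 1 m/s near
t ≈ 0.14 T — an early-systolic peak with a short zero-flow segment in
late diastole. Any published carotid waveform can be substituted through
the config. The vein carries a constant counter-flow of 0.08 m/s.

Stenosis is modelled geometrically: a fraction `rate` ∈ {0, 0.1, …,
0.9} of the artery cells is occluded by a half-plane sweep growing
either rightward (+x) or downward (−y), with ties broken by ascending
cell index — so masks nest with increasing rate. Occluded cells carry
zero velocity; the residual lumen speeds up by the flux-continuity
coefficient c = 1/(1 − rate), capped at 4.0 because real stenotic jets
do not reach the inviscid continuity limit at severe occlusion (typical
peak jet velocities are ~4 m/s clinically). A user-supplied
rate→coefficient table overrides the default, so a CFD-derived relation
can be dropped in. Whether the occlusion also leaves the conductivity
model is genuinely ambiguous ("removing a portion of the artery" vs.
"velocity set to 0"); the package defaults to conductivity-unchanged /
velocity-zeroed and exposes `stenosis_removes_conductivity` for the
other reading.

### Dataset

The full factorial is 5 field strengths (0.02–0.10 T) × 19 stenosis
configurations (10 rates × 2 directions, rate 0 once) × 86 time samples
(0.85 s at 0.01 s, inclusive endpoints — the inclusive convention is
forced by the published total of 8170 samples) = 8170 (U, v) pairs,
split 80/20 (6536/1634) by a seeded permutation. Voltages enter the
dataset exactly as the PDE produces them (volts, no rescaling); labels
are the reconstruction-window velocities in m/s, row-major. Since the
source is linear in both v and B, the generator factors the operator
once, solves per (stenosis, time) right-hand side, and scales the B
sweep exactly — identical to solving every sample independently, to
rounding.

## Networks

No deep-learning framework is used: layers (1×l convolution, transposed
convolution as the exact adjoint, max-pooling, bilinear width
upsampling, batch-norm, dropout, dense), the Adam optimizer and MAE loss
are implemented in NumPy with explicit backpropagation, verified against
numerical gradients to 1e-4 relative on a composite network. Training
is float64 and bit-reproducible given the seed. All kernels have height
1, so every window operation acts along the width axis only.

The reference CAE compresses 11×2601 → 11×11×60 through three
conv-conv-pool blocks (kernels 602/1001/201, 401/201/101, 51/26/15;
filters 2, 4, 8, 16, 32, 60; all tanh) and mirrors back through
bilinear-deconv-deconv blocks to 11×2601×1. All convolutions and pools
are stride-1 valid — the published output sizes force this — except the
first two decoder deconvolutions, which the sizes force to stride-2
same. The reconstruction CNN is three conv+BN+activation+pool blocks
(sigmoid, sigmoid, relu), flatten (1584 at reference width), a dense
relu layer of n units, dropout 0.5, and a linear dense output. The BP
baseline is 11 → 512 relu → n (architecture unspecified upstream; this
is the package's choice).

Training protocol at reference scale: CAE 3000 full-batch iterations at
lr 1e-4 (the single weight matrix is the whole batch); CNN 1500
iterations at lr 1e-5 with batch 817; Adam β₁ = 0.9, β₂ = 0.999,
ε = 1e-8. The weight matrix is globally z-scored before the CAE; v′
features are z-scored per entry over the training set; labels are
trained in m/s directly (optional z-scoring exists but defaults off).
Batch-norm statistics are frozen at inference; dropout is inference-off.

Initialization is Glorot-uniform for weights with a small positive bias
(0.1) on dense layers. The positive bias matters: with MAE's sign-based
gradients and labels that are ~80% exact zeros, zero-bias dense layers
let the first fully-connected ReLU die wholesale early in training and
the network collapses to a constant (per-cell median) predictor; the
positive bias keeps the layer alive through the initial
median-matching phase.

### Domain transformation

v_sub = W_sub⁻¹ U per channel. Learned encoders can emit
near-singular channels, so channels with condition number above 1e8
fall back to the Moore–Penrose pseudo-inverse and are recorded in a
conditioning report — an extension beyond the idealized always-invertible
assumption, in the name of robustness. The transform is exactly linear
in U and preserves channel order.

## Evaluation

Per-sample RMSE and Pearson CC between v̂ and v, averaged over a seeded
random half of the test split (mirroring an 817-of-1634 draw). As
printed, the CC denominator upstream mixes v̄ into the v̂ deviation
term; this is treated as a typographical slip and standard Pearson
correlation is implemented. Noise robustness is tested by adding white
Gaussian noise to the voltages at SNR = 20 log10(U_rms/noise_rms) for
60–20 dB before reconstruction, with the same evaluation subset
throughout. The Tikhonov weight λ is selected on a held-out slice of the
training split from a logarithmic grid scaled by ‖WWᵀ‖; on noiseless
validation data this drives λ toward zero (the minimum-norm solution),
which is faithful to the tuning rule but makes the baseline very
noise-sensitive — visible in the benchmark's noise sweep.

## Scaled benchmark

Training the reference-width networks on the 8170-sample dataset is a
multi-hour job, so the shipped benchmark scales the study down while
preserving its structure: 21×21 reconstruction window (n = 441), one
field strength (0.10 T), all 19 stenosis configurations, 10 time samples
(190 samples, 152/38 split), reduced-width networks that keep the exact
block patterns (CAE plan 441 → 340/170/136/100/60/52/26/13 → 11 with
p = 12 channels; CNN first kernel 7, pools 2/2/2), CAE 800 iterations at
lr 3e-3, CNN 500 iterations at lr 1e-3, BP 300 iterations. The whole
pipeline runs in about a minute on one CPU.

On this benchmark the CAE-CNN chain beats the tuned Tikhonov baseline on
both mean RMSE and mean CC, noiseless and at every tested SNR, and all
methods degrade monotonically from 60 to 20 dB — the qualitative
structure of the full-scale comparison. One ranking does not carry over:
at this scale the plain fully-connected baseline slightly outperforms
the CAE-CNN chain. With 152 training samples and a 12-channel encoder,
the feature expansion cannot yet pay for its extra variance; the
advantage of the transformation chain is expected to grow with dataset
size and channel count, as in the full-scale setting.

## Numerical choices and limitations

- Direct sparse LU for all conduction solves; tolerance-free. Non-finite
  solutions raise instead of propagating.
- Harmonic face averaging makes zero-conductivity cells exact insulators;
  their potentials are pinned to 0 and excluded.
- Stenosis tie-breaks, ROI ordering and split permutations are all
  deterministic given the seed; every random stream is derived from the
  single run seed via named SeedSequence substreams.
- The phantom is 2D: no axial return currents, no lead-field spread
  along the neck, no cardiac-cycle geometry changes, no contact
  impedance, and no competing bio-potentials (ECG-range interference is
  explicitly out of scope). Passing benchmarks here demonstrates the
  reconstruction chain on data whose physics matches the forward model's
  assumptions — not clinical readiness.
- The stenosis–velocity coefficient is an idealized continuity relation
  with a cap, not a CFD result; the override table is the hook for
  something better.
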