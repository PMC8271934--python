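# Methods

This note records the models, numerical choices, and defaults behind
`megloc`, and what the shipped desk-scale experiments do and do not
demonstrate.

## Forward model

The field of a current dipole at `p` with moment `q` inside a
spherically symmetric conductor is computed with the Sarvas closed
form; each sensor reports the field projected on its orientation.  Key
consequences, both enforced by tests:

* the field is linear in `q`, so an M×3 lead field `L(p)` captures a
  location completely and the mixing matrix `A(P)` has the topography
  `L(p_q) q_q` in column q;
* the radial component of `q` is silent outside the conductor, so
  lead fields have effective rank 2 and only tangential sources are
  observable.

A realistic-anatomy pipeline (cortical surface, overlapping-spheres or
BEM lead fields) is deliberately out of scope: the single-sphere
solution is exact and dependency-free, and every quantity studied here
(SNR, correlation, misregistration response) only needs the linear
structure above.  The lead-field provider is a contract — any callable
producing `(n, M, 3)` arrays per grid, such as `PrecomputedLeadField`
loaded from an HDF5 container, can stand behind the simulator and
scanner.

Geometry defaults: conductor radius 0.09 m centered at the origin
(adult head scale); 306 radial magnetometers quasi-uniform on a
spherical cap of 110° half-angle at 1.25 conductor radii (radial
sensors make the primary-current Biot–Savart expression exact for the
measured component, which gives the test suite an independent
closed-form oracle); source shell at 0.8 R = 72 mm with deterministic
tangential moment directions.  Sources within 1 mm of the center are
rejected (the closed form degenerates there).  SI units internally;
millimeters only in reports.

## Simulator

Each trial draws Q distinct grid points uniformly, builds 16-sample
time courses at fs = 1 kHz, synthesizes `Y = A S`, and adds white
Gaussian noise scaled so the Frobenius-norm SNR is exact per trial:
`||Y_clean||_F / ||N||_F = 10^(snr_db/20)` (amplitude-dB reading of the
norm ratio).  Time courses are equal-amplitude mixtures of three
sinusoids with frequencies uniform in 10–90 Hz and random phases; for
Q ≥ 2 the rows are mean-centered, Gram–Schmidt-orthonormalized and
mixed with the Cholesky factor of the Q×Q equicorrelation matrix, so
every pairwise Pearson correlation equals rho *exactly* (tested to
1e-6).  Centering is required for the Pearson guarantee; the number of
sinusoids per mixture (3) is a free choice and configurable.

Single-snapshot trials (N = 1) have no usable notion of sample
correlation; each source then contributes a unit-magnitude amplitude
of random sign.  Ground-truth rows are sorted lexicographically by
(x, y, z) so the regression target is deterministic; evaluation is made
permutation-invariant separately.  The batch streamer re-implements the
same construction vectorized over trials and is a pure function of its
master seed (bit-identical streams across runs).

What the generator does **not** emulate: structured brain noise,
correlated sensor noise, artifacts, realistic cortical geometry,
amplitude variation across sources, or minimum inter-source distance.
Passing tests therefore certify the algorithms under the stated ideal
conditions, not performance on real recordings.

## Networks and training

Six declarative architectures (three single-snapshot MLPs, three
multi-snapshot CNNs for Q = 1, 2, 3) reproduce their published
parameter totals exactly; the conv layer is pinned to a full
cross-channel 1-D convolution (32 kernels of length 5, valid padding,
sigmoid activation after bias) because that is the unique topology
whose count matches the printed totals — per-sensor depthwise variants
do not.  Convolution is implemented as cross-correlation, the common
deep-learning convention; with learned kernels the distinction is
immaterial.  Forward pass, backpropagation and SGD are plain NumPy,
which keeps the reference path deterministic and directly
finite-difference-checkable (gradients agree to < 1e-5 relative).

Regression targets are coordinates relative to the sphere center
divided by the source-shell radius, so they lie in [−1, 1].  Inputs are
normalized per sample to unit-RMS entries — dividing by the Frobenius
norm removes the arbitrary field amplitude, and the sqrt(size) factor
keeps per-entry variance near 1, the regime fan-based (Glorot-style)
initialization assumes.  Weights start from fan-based uniform limits
with the gain-4 sigmoid correction (sigmoid(z) = 1/2 + z/4 near zero,
so gain-1 limits shrink signal variance 16-fold per layer and leave
deep sigmoid stacks stuck near mean prediction at desk-scale budgets);
the linear output layer keeps gain 1.  The overall sign of each sample is also
canonicalized (largest-magnitude entry made positive): source polarity
is unidentifiable from the field pattern, so the target is an even
function of the raw measurement, and near-linear sigmoid layers escape
that parity obstruction extremely slowly if it is left in the data.

Training protocol: MSE on normalized coordinates, batch size 32,
learning rate 0.001.  Plain SGD is the reference update; the shipped
desk-scale configurations use the momentum variant (0.9), without which
the width-reduced sigmoid stacks do not leave the mean-prediction
plateau within the scaled step budgets.  No early stopping, no
regularization, no schedules.  Scaled budgets: 20k steps for the MLP
(640k simulated snapshots) and 6,250 steps for the CNN (200k
multi-snapshot trials), against the full-scale 1M/9.6M-sample
protocol; full budgets are one config change away.

## RAP-MUSIC baseline

Signal subspace: top-Q left singular vectors of `Y` directly (no
explicit covariance — safer for N = 16 ≪ M = 306; a test confirms
equivalence with the covariance eigendecomposition).  A single
snapshot degenerates to the rank-1 span of the data vector, and a
rank-deficient window caps the subspace with a warning while the
recursion still extracts Q dipoles.

Localizer: largest canonical correlation between `span L(p)` and the
signal subspace, computed by rank-truncated orthonormalization of
`L(p)` (singular values below 1e-10 of the largest are dropped —
spherical lead fields are rank 2) followed by an SVD of the
cross-basis product; the maximizing moment direction is recovered
through the truncated pseudo-inverse.  A 1°-resolution brute-force
orientation sweep serves as the independent oracle (agreement to
1e-4).

Recursion: after each find, the *oriented topography* of the found
dipole is stacked and both the subspace and all candidate lead fields
are projected onto its orthogonal complement and re-orthonormalized.
Note the free-orientation consequence: the orthogonal tangential
direction at a found grid point retains nonzero correlation, so the
localizer at that point does not vanish — only the found topography
does.  Grid argmax ties break to the lowest index; there is no
off-grid refinement.  The scan is vectorized over the grid: each lead
field is reduced once to its two non-silent principal directions, the
recursion updates the reduced Gram matrices algebraically, and the
per-point generalized Rayleigh quotients are solved with closed-form
2×2 eigendecompositions — a 2,000-point scan costs ~10–25 ms, which
makes the Monte-Carlo suites tractable (imported full-rank lead fields
fall back to a general SVD path).

## Evaluation

The error metric is the minimum over all Q! source-to-estimate
assignments of the mean Euclidean distance, in millimeters (brute-force
enumeration, Q ≤ 3; cross-checked against an optimal-assignment
solver).  Experiments report mean, standard error and median over
repetitions; the no-information reference is the mean distance between
two uniform-random grid points (≈ 4r/3 ≈ 96 mm for the 72 mm shell).

Three drivers mirror the study protocol at desk scale (200 repetitions,
2,000-point grid, width-scale-0.1 networks, versus 1000 repetitions, a
15,002-point cortical grid and full-width networks at full scale):

1. single-snapshot MLP vs RAP-MUSIC across inference SNR (−10…20 dB),
   network trained at 10 dB only;
2. multi-snapshot CNN vs RAP-MUSIC across rho ∈ {0…0.9} and SNR, for
   two and three sources, network trained at −15 dB with random rho;
3. misregistration robustness: test data generated after rigidly
   translating (3 mm) or rotating (1°) the source space — orientations
   rotate with it — while the network keeps its unperturbed-model
   weights.  Trials are paired across perturbations (common random
   numbers), so the identity perturbation yields degradation exactly 0
   and degradation estimates are low-variance paired differences.

At desk scale the absolute error levels of the full-scale study are
not reproducible; the shipped suites therefore assert *trend*
properties (error decreasing in SNR, non-decreasing in correlation,
both methods beating the no-information baseline, exact noiseless
recovery) plus the robustness *bounds* (translation degradation
≤ 1 mm, rotation degradation ≤ 0.25 mm), which are scale-robust
because a network's response to a millimeter-scale geometry change is
a smooth perturbation of its input distribution.  The timing harness
reports median wall-clock per inference and is hardware-dependent by
nature; only the ordering (forward pass faster than grid scan) is
asserted.

## Known limitations

* The sphere model cannot represent radial sources; real cortical
  dipoles have radial components that a realistic head model would
  partially see.
* Mixed gradiometer/magnetometer arrays need a unit-scaling or
  whitening scheme that is intentionally not guessed here; the default
  array is homogeneous radial magnetometers.
* The scaled networks are far from converged relative to the
  full-scale protocol; their absolute errors mainly demonstrate that
  the training loop learns, not the accuracy ceiling of the approach.
* Estimating the number of sources Q is out of scope; all methods
  assume it known.
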