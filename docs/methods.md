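# Methods

## The model in brief

The agent closes a perception-action loop: sparse coding of binocular
spatio-temporal image patches provides both the reward (negative
reconstruction error, an intrinsic measure of coding efficiency) and the
state (per-atom mean squared coefficients) for a natural actor-critic that
moves the eyes.  Stabilizing the stimulus on both retinas — verging at the
right depth, pursuing at the right speed — maximizes the redundancy between
the four subfields of each patch and is therefore the behavior that sparse
coding rewards.  Nothing else is optimized: fixation and pursuit emerge.

## Virtual rig

The renderer replaces a physics simulator with exact pinhole geometry:
cameras at (±0.034, 0, 0) m, horizontal FOV 90° at 320 × 240 px (focal
length 160 px), pan/tilt applied conjugately to both cameras and vergence
split symmetrically (∓ξ/2 toe-in, which is the geometry implied by
ξ* = 2 arctan(d_E/2d_O)).  The stimulus is a 1.5 m × 1.5 m fronto-parallel
textured plane; a pink-noise background plane sits at 6 m.  Texture lookup
is bilinear with edge clamp; rays missing both planes render mid-gray.
Angular stimulus velocities are applied about the cyclopean origin
(x = z·tan α), so "deg/s" is exact at every depth.  Non-goals: lens
distortion, lighting, occlusion, motor latency, torsion, accommodation.

Eye kinematics use semi-implicit Euler with dt = 0.1 s (velocity before
position), matching action units of deg/s² for pan/tilt and deg for
vergence.  Joint limits (|pan|, |tilt| ≤ 15°, ξ ∈ [0.2°, 16.3°]) are
inclusive; a violation zeroes the joint velocities and re-fixates, and also
clears the two-step RL buffer and the previous-frame patch memory, since
the gaze discontinuity invalidates both temporal pairings.

## Stimuli

The procedural stimulus set cycles through three generators: pink noise
(1/f radial amplitude spectrum — the second-order statistics of natural
images), superimposed oriented step edges with cardinal orientations drawn
with probability 0.7 (the horizontal/vertical prevalence of man-made
scenes), and axis-aligned random rectangles (pure cardinal structure).
What these do **not** emulate: higher-order statistics of real scenes
(textures, contours, shading), chromatic content, and depth structure
within the stimulus (the plane is flat).  Tests passing on these stimuli
show the architecture works and learns where redundancy exists; they do not
certify performance numbers on natural photographs.

## Preprocessing choices

- Whitening is applied once to the full 320 × 240 frame before sub-window
  extraction; radial frequency is measured in cycles per image relative to
  the larger side (so f₀ = 96 means 96 cycles across the 320 px width).
- The Gaussian pyramid uses the 5-tap binomial kernel [1,4,6,4,1]/16,
  reflect boundary, two reduce steps for the ×4 factor.
- Normalization (zero mean, unit norm) is per 8×8 monocular single-time
  subfield; a subfield with norm < 1e-8 after mean subtraction is kept as
  zeros.  The assembled 16×16 patch is *not* renormalized (its norm is 2
  for non-degenerate subfields); the reconstruction error divides by each
  patch's own squared norm, so this convention only fixes the overall
  scale of coefficients and reward.
- At the first frame of an episode the t−1 subfields are copied from the
  current frame (a static view), so no content leaks across episodes.

## Sparse coding

Matching pursuit runs exactly 10 iterations per patch; atoms may be
reselected, with coefficients accumulating (sparsity is enforced as an
iteration budget, so distinct non-zeros can be fewer than 10).  Ties in
atom selection go to the lowest index.  The dictionary gradient step uses
the final accumulated coefficients and the final residual,
Δφ = η·κᵀ(p − p̂)/|p|, η = 0.5, followed by renormalization of every atom
to unit energy; atoms never selected receive no update.  Gabor
initialization draws each of the four subfields independently:
λ ~ U[8/3, 16] px, θ ~ U[0°, 180°], ψ ~ U[0°, 360°], centers
x_c, y_c ~ U[8/3, 8] px, σ = 2.5 px, β = λ/6.4, on the integer pixel grid
0..7, mean-subtracted and unit-normalized per subfield before the joint
energy normalization.

## Reinforcement learning

The TD error is implemented exactly as specified for this architecture —
δ_t = r_t − Ĵ_t + γ·V(s_t) − V(s_{t−2}) with γ = 0.3, ξ = 0.01 for the
average-reward filter, α = 0.4 for the critic — with both value terms
evaluated under the *current* critic weights (the advantage-parameter NAC
family carries a single parameter vector).  Ĵ is updated with r_t before δ
is formed.  Actors: softmax with T = 1 over the 13-action set; advantage
parameters w per actor updated with β = 0.16; θ ← θ + 0.4·w using the
*updated* w.  All three actors consume the same δ from the single critic.
Weights start at zero (uniform initial policy).  No updates occur in the
first two iterations after an episode start or gaze reset, because the
(s_{t−2}, a_{t−2}) pair does not exist.  State vectors are fed to the RL
stage unnormalized.

A practical note on operating regime: the advantage-parameter update has a
momentum-like character (θ integrates w), and with order-one state vectors
and order-ten rewards it can saturate the softmax on a near-optimal action
before averaging has resolved fine action distinctions.  The deployed
architecture operates with state entries of order 1e-2 and is well-behaved
there.  The contextual-bandit convergence check therefore uses one-hot
states scaled to 0.02, rewards normalized by the largest action magnitude,
and 5·10⁴ updates; under these frozen settings the greedy policy cancels
the error exactly in ≥ 90% of bins on every probed seed, with residual
confusions confined to actions within one quantum of the optimum (the same
resolution limit the full agent shows for small errors).

## Training, testing, profiles

Full-scale training is 5·10⁵ iterations, |B_S| = 600, 100 stimuli, with 10
evenly spaced checkpoints (final iteration included).  The desk profile
(5·10⁴ iterations, |B_S| = 200, 10 stimuli) exists so a single-CPU machine
can run the whole protocol in hours rather than days; both are plain YAML
files under `configs/`.  The default unit-test suite goes one step smaller
(hundreds of iterations, |B_S| ≤ 100) — enough to verify mechanics,
determinism and the direction of learning, not endpoint performance.
Test trials place each stimulus at a depth drawn from U[1, 2.5] m with a
per-trial RNG derived from the trial index, so the 10,800-trial grid is
reproducible and identical across the checkpoints being compared.  The
random-action control (RNDCTL) keeps critic and actors frozen and samples
actions uniformly; the dictionaries keep learning.

## Receptive-field analysis

Each 8×8 subfield is fit with A·g(x, y; λ, θ, ψ, σ, β, x_c, y_c) by
multi-start nonlinear least squares (17 starts: one seeded from the
dominant Fourier component and the |subfield| centroid, plus a 4×4 grid
over θ × ψ; box bounds are generous supersets of the initialization
ranges; the model is mean-subtracted and the amplitude solved in closed
form by variable projection).  A start that explains all but 1e-3 of the
energy stops the search.  The reported residual r is the squared residual
norm of the subfield *at its natural scale inside the unit-energy atom*
(each subfield carries ≈ 1/4 of the atom's energy), so r ≈ 0 means
"exactly Gabor" and r ≈ 0.25·(1 − q) for a fit explaining a fraction q of
the subfield; the scale-free fraction is available as `r_frac`.  This
convention is what makes the two calibration anchors meaningful: fresh
Gabor dictionaries give mean r ≈ 0, unit-energy white-noise atoms give
mean r ≈ 0.18.

Disparity and velocity preferences derive from fitted carrier phases
*referenced to the patch origin* (ψ₀ = ψ − 2π(x_c cosθ + y_c sinθ)/λ):
a spatial displacement of a pattern can be absorbed into the fitted
envelope center, so center-referenced phases of two independent fits are
not comparable.  Phase differences are wrapped to (−π, π].  An atom enters
the tuning table only if all four subfield fits leave r_frac ≤ 0.5; a
left/right (or t/t−1) pair with wavelengths differing by > 10% or
orientations by > 10° is flagged and excluded from that preference, as is
disparity for near-horizontal orientations (|cos θ| < 0.1, where
horizontal disparity is undefined).  Orientation histograms use the
time-t left subfield with bins centered on the cardinals.  θ = 0° denotes
vertical stripes (horizontal carrier modulation).

## Degenerate inputs and tie-breaks

Zero patches encode to empty codes and contribute zero to E_S and the
state; greedy action ties resolve to the smallest-magnitude action (an
untrained agent holds still rather than lurching); dictionary atoms with
zero norm after an update (cannot occur in practice) are left untouched by
renormalization; a stimulus plane reaching 0.05 m depth aborts the episode
and a fresh one is placed.

## Known limitations

Endpoint performance numbers of multi-day full-scale runs (final error
medians, trained-dictionary residuals, tuning correlations) are outside
the default test envelope; the desk profile reproduces their direction,
not their printed values.  The renderer supports fronto-parallel planes
only — slanted/tilted or curved stimuli are out of scope.  The procedural
textures bound what the tuning analyses can show about natural-scene
statistics (the cardinal orientation bias is put in by construction, not
discovered).
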