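# Methods

## Problem and model

The package estimates a *continuous gait phase* — an angle in (−π, π] that
advances monotonically through each stride — from planar marker kinematics,
in real time and without phase labels. The observable per side is the ankle
position relative to the iliac crest,

    R_x[t] = x_ankle[t] − x_iliac[t],      R_y[t] = y_ankle[t],

which removes whole-body progression, so treadmill and overground walking
present the same signal up to noise. Both series are standardized to zero
mean and unit variance using statistics of the *training* pool only
(population, 1/n, standard deviations, so the training pool standardizes to
exactly unit variance). Each sample also carries a *heading direction* per
axis: the ordinary-least-squares slope of the 7 samples ending at that
sample (causal; the abscissa is the sample index — any fixed time scale is
absorbed by the heading normalization, which reuses the training pool's
heading mean/sd). A *feature window* ending at sample i stacks standardized
x, y and the two normalized headings for samples i−6…i: 4 features × 7
samples = 28 inputs. Because each heading looks back 6 further samples, the
first window of a stream needs 13 samples (86.7 ms at 150 Hz); afterwards a
new window arrives with every sample.

The phase network is a fully connected stack
28 → 25 → 25 → 25 → 25 → 25 → 2 with tanh after the first four hidden
layers and identity activations from the fifth hidden layer into the 2-node
*pre-phase* output V (3377 parameters). V is Euclidean-normalized onto the
unit circle; its angle is the phase, and its magnitude is the distance from
the singular configuration V = 0 at which the phase is undefined.

## Training objective

Training is unsupervised. For a batch of N pairs of *consecutive* feature
windows (ending at samples i−1 and i), with (x̄, ȳ) the unit-circle output
of the previous window and (x̂, ŷ) of the current one:

* **Phase progression (PP)**, weight 1. The signed advance
  ν = arctan2(x̄ŷ − x̂ȳ, x̄x̂ + ȳŷ) is scored by a piecewise-cosine
  penalty P(ν) that is exactly zero on the free band (a, b], rises along
  cosine flanks to a maximum of 1 at ν = c, and is continuous around the
  circle. Parameters a = −2.3π/180, b = 4π/180, c = −135π/180: consecutive
  windows may advance up to 4° or retreat up to 2.3° per sample freely; at
  150 Hz and 0.7–1.3 strides/s the true per-sample advance is 1.7–3.1°, so
  a phase locked to the gait cycle is penalty-free. The asymmetry
  (|a| < b) favors anticlockwise progression.
* **Distribution (D)**, weight α = 0.45: α times the squared distance of
  the centroid of current-window unit vectors from the circle's centre —
  zero when phases cover the circle evenly, α on collapse.
* **Singularity (S)**, weight γ = 0.55: mean Gaussian bump
  g(|V|) = exp(−|V|²/2σ²)/(σ√2π) of the raw pre-phase magnitudes, pushing
  the output away from the origin.
* **Marginal singularity (M)**, weight λ = 0.55: the same bump applied to
  pre-phase vectors of inputs perturbed with zero-mean Gaussian noise of sd
  σ_w on all 28 dimensions (positions and normalized headings), redrawn
  every iteration. It penalizes solutions whose decision boundary passes
  close to the data.

σ (Gaussian width, default 1.0) and σ_w (input noise, default 0.3
standardized units) are free parameters of the method. σ_w was fixed from a
convergence study on the training loss: at σ_w ≲ 0.1 the M term almost
never probes the thin transition regions of a degenerate solution and
training can collapse onto two antipodal output clusters connected by
180°-jumps (which zero D and almost zero PP); at σ_w ≈ 0.3 the winding of
the learned map locks onto one wrap per gait cycle.

Gradients are computed analytically in reverse mode over numpy arrays (the
graph is short: six affine layers, tanh, normalization, arctan2, and the
piecewise profile) and are validated against central finite differences to
1e-4 relative error in the test suite. The optimizer is Adam
(lr 1e-3, β = 0.9/0.999), full-batch by default with an optional uniform
minibatch per iteration; the default protocol is 10,000 iterations, and the
scaled-down experiments below use 2,000 with minibatches of 1,024 pairs.

## Initialization, topology, and restarts

The loss landscape contains degenerate basins in which the phase dwells and
then jumps; three deterministic, label-free mechanisms address them:

1. **Zero-bias initialization.** Weights are U(±1/√fan_in); biases start at
   zero, making the initial network an odd map. The standardized input loop
   is roughly centred, so its image encircles the pre-phase origin — the
   winding the solution needs. With random biases the origin frequently
   falls outside the image loop, and the singularity terms make that wrong
   topology expensive to correct later.
2. **Direction alignment.** The band (a, b] rewards anticlockwise
   progression; an initialization that happens to wind clockwise along the
   training stream can only comply through a topology-changing flip that
   the S/M terms obstruct (runs stranded mid-flip were a repeated failure
   mode). The initial winding over the training windows is measured and, if
   negative, the second pre-phase output is negated (V_y → −V_y), which
   reflects the map and reverses the winding with no other change.
3. **Restarts.** Some initializations still end badly. Early loss does not
   predict the final basin (verified empirically: losses after 300
   iterations are uncorrelated with the outcome at 2,000), so
   `TrainConfig.n_starts` (default 4) full-length runs are trained from
   independent seeded initializations and the lowest final full-batch loss
   — clean solutions reach ~0.003 or less, degenerate ones plateau an order
   of magnitude higher — selects the returned network.

All three use only the training features; everything is reproducible from
`TrainConfig.seed`.

## Events, calibration, and scoring

Ground-truth heel strikes are positive peaks of R_x (foot horizontal
velocity + → −) and toe-offs negative peaks, found with a minimum
separation of half the dominant period (from the autocorrelation's first
peak) and a prominence floor of 25% of the peak-to-peak range. Calibration
reads the model phase at ground-truth events on *training* data and takes
circular means (resultant-vector angle; a resultant length below 0.1, e.g.
antipodal phases, is rejected as degenerate); the progression direction is
the sign of the median phase step, and clockwise models are handled by
reflection through that direction. Detection on unseen data is causal: an
event fires when the phase crosses its reference in the calibrated
direction, with at most one detection per reference per cycle (refractory
interval of half the dominant period). Scoring matches each truth event to
the nearest detection of the same type within half the median inter-event
interval; the report is the absolute error in ms over matched events, with
unmatched events counted separately rather than assigned an arbitrary
error.

Phase agreement with the synthetic ground truth is the Fisher–Lee
circular–circular correlation in its pairwise form (computed in O(n) via
product-to-sum identities). The pairwise form is used deliberately: the
deviation-from-circular-mean variant is unstable when phases wind uniformly
around the circle (the mean resultant length is then near zero and the
circular mean arbitrary). The statistic is rotation-invariant; reflection
flips its sign, so clockwise models are reflected before comparison.

## Synthetic gait generator

One simulated side is a closed-form periodic trajectory with known phase:
the forward-back excursion is amplitude_x·cos(u(φ)), where the monotone
piecewise-linear warp u maps stance onto [0, π) and swing onto [π, 2π), so
heel strike (x maximum) sits at phase 0 and toe-off (x minimum) at the
stance/swing boundary; vertically the ankle rests at baseline_y during
stance and lifts by amplitude_y·sin²(π·swing progress) during swing. Right
leads left by π. The iliac crest moves at progression_speed (0 =
treadmill-like) with optional sinusoidal sway; i.i.d. Gaussian noise of sd
noise_sd is added to every marker coordinate. Defaults are comfortable
adult walking recorded by optical motion capture: 150 Hz, 1 stride/s
(cohorts draw 0.7–1.3 strides/s per subject), ±300 mm forward-back
excursion, 80 mm foot lift, 100 mm ankle marker height, duty factor 0.6,
0.5 mm marker noise, 30 s per walk.

The generator reproduces the peak structure and periodicity that the
detector and its evaluation rely on, with analytically known events; it
does not emulate inter-stride variability, asymmetric or pathological gait,
soft-tissue artefact, marker dropout, or 3-D kinematics. Passing tests
therefore demonstrate that the method recovers phase and event timing from
realistic-amplitude periodic kinematics under measurement noise — not that
it handles the full variability of human data.

## Scaled-down experiment sizes

The packaged experiments use 20 subjects (12 train / 4 held out), 30 s
walks at 150 Hz, 2,000 training iterations with 1,024-pair minibatches, and
4 restarts; the speed-condition comparison uses 3 training and 1 test
subject per speed band, 20 s walks, and 1,000 iterations. These sizes were
chosen so the full suite runs comfortably on a desktop CPU while keeping
several thousand evaluation strides per run.

## Numerical choices and edge cases

* Angles live in (−π, π] throughout; wrapping maps −π to +π.
* A pre-phase magnitude below 1e-12 raises a singularity error (inference)
  or aborts the iteration with the offending pair index (training).
* Series shorter than 13 samples yield no windows — a warning, not an
  error; shorter than 14, no training pairs.
* The Gaussian normalizing constant 1/(σ√2π) is kept in S and M as printed
  in their definitions.
* D is computed over current-window outputs only; noise in M perturbs the
  current window of each pair.
* Phase range checks use a 1e-6 unit-norm tolerance; the penalty profile
  rejects ν outside (−π, π].

## Known limitations

* The free band (a, b] presumes roughly one sample of phase advance per
  window step; grossly different sampling rates or cadences require
  retuning a and b (guidance: b ≈ 2π / samples-per-cycle).
* Restart selection multiplies training cost by n_starts.
* Event detection assumes quasi-periodic input; the refractory and matching
  windows derive from a single dominant period and would mishandle strongly
  irregular gait.
* The synthetic cohort shares one kinematic shape family across subjects;
  real inter-subject shape variation is untested here.
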