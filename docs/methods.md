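# Methods

## Signal path and features

Recordings are 12-channel surface EMG at 1000 Hz (8 forearm/extrinsic and 4
hand/intrinsic electrode pairs), labelled per sample. Analysis windows are
*trailing* (causal): a window of length L ms is timestamped at its trailing
edge and spans the preceding L samples; consecutive windows advance by the
25 ms frame increment. A recording of T ms therefore yields
`floor((T − L)/25) + 1` windows.

Each window yields 10 features per channel, concatenated in channel order:

* **MAV** — mean absolute value.
* **ZC** — zero crossings. A sample pair counts when its signs differ or
  exactly one sample is zero, and the amplitude step exceeds the dead-band
  threshold (default 0). Counting a zero-valued endpoint as a crossing keeps
  the sampled count of a pure sinusoid equal to the analytic crossing count.
* **SSC** — slope-sign changes: strict local extrema whose neighbouring
  slopes both exceed the dead-band (default 0).
* **WL** — waveform length (sum of absolute successive differences).
* **AR(6)** — autoregressive coefficients in the positive convention
  `x_t = Σ aᵢ x_{t−i} + e_t`, fitted by the autocorrelation (Yule–Walker)
  method: the single-window path solves the Toeplitz system by Levinson
  recursion, the pipeline path solves the same systems batched; both add a
  relative ridge of 1e−9 on the zero-lag term so near-degenerate windows
  (e.g. pure tones) stay solvable, and a zero-variance window returns all
  zeros by convention. Burg's method is available as a config option and
  agrees with Yule–Walker on stochastic EMG-like signals.

These choices — the Hudgins time-domain set plus order-6 AR — are the
canonical feature family for this controller lineage.

## Classifier

Gaussian LDA: per-class means, pooled within-class covariance
(denominator n − k), shrinkage `γ · trace(S)/d · I` with γ = 1e−6 by default
(the evaluation studies use γ = 1e−2, because some training conditions fit
120-dimensional features from only ~80 windows). Priors are equal by default:
class balance is set by the collection protocol, so estimating priors from it
would only encode protocol bookkeeping. Ties in the discriminant argmax break
toward the earlier class in the model's class list; class order defaults to
first appearance and the studies pass the canonical order explicitly
(no-movement, hand-open, then grasps by ADL usage).

The grasp-maintenance classifier is **re-trained** on remapped labels (all
grasps → hand-close) rather than post-hoc mapping of N+2-class outputs; the
3-class boundary differs from the union of grasp boundaries, and re-training
is what "the classifier selects between these three classes" describes. The
N+2-class variant remains available (`three_class=False`).

## Controller semantics

* **Mode** — aperture ≥ 0.99 (inclusive) is fully open → selection mode;
  otherwise maintenance.
* **Voting** — the vote buffer holds the trailing raw decisions spanning one
  current-mode window (window/25 votes). The plurality class wins if it holds
  ≥ 50 % of the *possible* votes; shortfall or a tied plurality defaults to
  no-movement. Mode switches clear the buffer (votes from the other mode's
  alphabet are meaningless). Votes accrue during a freeze (configurable).
* **Delay** — the freeze engages on the maintenance→selection transition
  (the frame that detects full opening). That frame does not accrue grasp
  time; each subsequent frame carrying a grasp decision adds 25 ms, hand-open
  or no-movement resets the timer, and the freeze releases once the timer
  reaches **half the current window length** (inclusive). This is the only
  reading under which the minimum freeze equals exactly 125 ms (static) and
  250 ms (dual), as the mechanism's stated minima require; a strict "greater
  than" would overshoot by one frame.
* **Speed** — mean-channel MAV rescaled linearly between calibrated rest and
  maximum levels (clamped to [0, 1]), multiplied by a linear 500 ms velocity
  ramp that accrues while the decision class repeats and resets on any class
  change or no-movement. The cited ramp's exact shape is not specified in the
  source material; linear is assumed. Frozen frames and no-movement frames
  command zero speed.

## Virtual hand

One aperture degree of freedom in [0, 1]; commanded speed integrates linearly
with `full_excursion_s = 1.5 s` for the whole range at unit speed. The value
is a design choice — no plant dynamics are given for the original VR hand —
picked so that a full closure takes ~1.5–3 s under typical proportional
speeds, consistent with multi-attempt trials fitting a 15 s timeout.
Evaluation therefore relies on relative/structural properties, never absolute
closure times. Grasps latch: engagement only from the fully-open position
(aperture ≥ 0.99), a different grasp while latched is ignored, and reaching
fully open clears the engagement. Open/closed tests use 0.99/0.01 tolerances
to avoid float equality.

## Synthetic EMG

Each channel is amplitude-modulated AR-coloured Gaussian noise passed through
a 4th-order Butterworth 30–350 Hz band-pass (the acquisition filter; ≥ 95 %
of power lands in band). Structure:

* **Class signature** — a per-(class, channel) RMS gain table (Gaussian bumps
  of activation centred at class-specific channel locations plus a fixed
  perturbation) and a per-class AR(6) spectral prototype. `class_contrast`
  scales inter-class gain differences; no-movement is noise floor only.
* **Wrist confound** — static positions multiply channel gains by
  `exp(depth · u)` with u ∈ [0.3, 1] per (position, channel), depth 0.35 on
  extrinsic and 0.05 on intrinsic channels, so wrist state shifts extrinsic
  amplitudes by up to ~40 % while barely touching intrinsic ones. Dynamic and
  hybrid trajectories interpolate the log-factors along the movement.
* **Transients** — movement classes ramp up linearly over 200 ms with a
  decaying broadband admixture, so "transient EMG" testing is meaningful.
* **Variability** — lognormal per-repetition channel jitter (σ = 0.22) and an
  additive band-limited noise floor (RMS 0.04).

Defaults were calibrated once so the 8-class selection error under
neutral-only training lands mid-range (~15–30 % across seeds) while
well-trained conditions stay low — leaving room to demonstrate both the
improvement from richer training data and the degradation from the wrist
confound. `SynthConfig.well_separated()` provides a low-noise world for tests
needing a near-ideal subject.

What the generator does **not** model: motor-unit physiology, electrode shift
or impedance drift, fatigue, crosstalk geometry, or real inter-class effect
sizes (unknowable from the source material). Passing trend tests therefore
demonstrates that the *control system* responds to confound structure and
post-processing the way the mechanisms predict — not that human-subject error
magnitudes are reproduced. Headline human-study magnitudes are out of scope
by design.

The simulated subject streams the same generative model causally (filter
states carried across 25 ms chunks, first-order envelope slew with ~200 ms
onsets) and adds an imperfection model: brief accidental activations at
`burst_rate_hz` (default 0.3/s in the evaluation) that switch the emitted
pattern to a confusable class (another grasp or hand-open) for 100 ms.
Bursts shorter than the delay threshold and the voting majority are exactly
the events those techniques are designed to reject, while a single wrong
frame suffices to mislatch the unmodified classifier — the mechanism behind
the selection-attempts comparison.

## Offline study conventions

* Folds: repetitions alternate in collection order (reps 1,3 → fold 0;
  2,4 → fold 1); splitting is by repetition, never by frame.
* "First 600 ms" → windows whose trailing edge ≤ 600 ms; "all but the first
  300 ms" → windows entirely after 300 ms (trailing edge ≥ 300 + L). With a
  4 s trial and L = 200 this gives 141 steady-state windows (ends 500…4000).
* Selection training uses windows ending within the first L+100 ms uniformly
  (stated for the grid analysis; applied globally for consistency).
  Maintenance classifiers train on the steady-state region (same rule as
  maintenance testing) in both analyses — one consistent transient/steady
  partition rather than two per-analysis variants.
* Selection is tested only on static-wrist trials (wrist prepositioned before
  selection); maintenance on static and dynamic trials (free wrist after
  selection).

## Real-time study conventions

* Trials: 2 s wrist prepositioning consumes simulated time but is excluded
  from scoring; the 15 s limit and all timestamps start at hand reveal.
* A selection attempt is a fully-open → partially-closed transition.
  "Correct grasp selected" is operationalised as the final such transition
  from which the trial completes without reopening; wrong-grasp closures
  count as attempts only. Selection time runs from reveal to that transition,
  completion time from there to full closure, so their sum never exceeds the
  15 s limit on completed trials.
* Classifier training (and the proportional-control calibration: rest = median
  no-movement MAV, max = 75th-percentile grasp MAV) is shared across the
  techniques of a windowing method, as one subject's training data would be.
* The subject model re-targets hand-open after a wrong grasp engages and
  resumes the target after fully reopening.

## Problem sizes

The statistical suites use the full protocol datasets (224 + 192 recordings
per world) with 10 independently seeded worlds for the offline trend means,
10 seeds × 28 trials × 3 techniques for the selection-attempts comparison
(static windowing; the technique effect is windowing-independent), and
8 random-label draws for the chance-level checks. These sizes were chosen so
the whole evaluation runs comfortably on a laptop-class single core while
keeping seed-to-seed variance well inside the asserted margins.

## Known limitations

* The controller runs frame-synchronously at 25 ms; computation time within a
  frame is not modelled.
* The plant is a single aperture DOF — no per-finger kinematics, grip force,
  or rendering.
* LDA only; no online adaptation; no inferential statistics — the package
  reports errors and metrics, not significance tests.
* Proportional-control and ramp formulas are linear assumptions where the
  source material defers to citations.
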