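# Methods

This note documents the models, numerical choices, and study conditions
behind `rangeadapt`: what the simulator generates, what the analysis stages
compute, and what the test batteries do and do not establish.

## Task geometry and data model

The workspace is a center-out task with targets 85 mm from the origin
(target and cursor radii 8 mm each). The 3D context uses the 26 normalized
nonzero vectors of the 3×3×3 grid — cube corners, edge midpoints, and face
centers — and the 2D context uses 16 equally spaced azimuths in the
xy-plane. Eight directions (planar, at multiples of 45° azimuth) are common
to both contexts; their stored coordinates are bit-identical across
contexts so that noiseless cross-context comparisons are exact. Coordinates
are right-handed (x rightward, y forward, z upward); azimuth is measured
counter-clockwise from +x, elevation positive above the plane; angles are
stored in degrees. Sessions round-trip through plain CSV/YAML files
(`trials.csv`, `units.csv`, `decoder.yaml`); an external `targets.csv` can
override the canonical geometry, with cross-context matching done by
angular tolerance (1e-6 rad) rather than id equality.

## Tuning models

Two per-unit tuning families are used throughout:

* **linear**: r(d) = b0 + m (d·p), fit by ordinary least squares on
  trial-mean rates; p is the normalized coefficient vector and m its norm
  (m ≥ 0, sign absorbed into p).
* **log-linear**: r(d) = exp(bll0 + mll (d·pll)), fit as a Poisson GLM with
  log link on spike counts, with log(duration) as offset so the linear
  predictor models the rate in Hz. The dispersion is the Pearson
  chi-square over residual degrees of freedom. Fits use statsmodels.

Planar (2D-context) fits regress on the two planar direction components;
the fitted direction is embedded with z = 0 for angle comparisons. Fitting
the 2D context with a 3-component regressor is impossible on planar-only
targets (the z column is identically zero), which forces this choice.

## Decoders

Population activity is normalized per unit, u_i = (r_i − b0_i)/m_i, and
decoded linearly:

* **PVA**: v = ks (nD/N) Σ_i u_i p_i, with speed factor ks (mm/s per unit
  normalized speed; default 90, the midpoint of the 65–120 range used in
  practice), nD the context dimensionality and N the population size.
* **OLE**: v = ks · pinv(B)(r − b0), the least-squares solution with B the
  N×3 matrix with rows m_i p_iᵀ.

We read the decoding equations' P and B as N×3 matrices (rows p_iᵀ and
m_i p_iᵀ): that is the only reading under which the products are 3-vectors,
and it makes the PVA the classic population-vector sum and the OLE the
pseudoinverse decode. The cursor integrates velocity every 33 ms; in the 2D
context the z-component of the decoded velocity is zeroed before
integration. The planar OLE decode solves the full 3-column system and then
zeroes z (matching the online implementation) rather than solving a reduced
2-column system. Online rate smoothing (mean of the last five 33 ms bins)
lives in the simulator's closed loop and is applied before normalization;
the decode operations themselves take already-smoothed rates.

## The simulator

Each session is a 3D block followed by a 2D block (configurable), with
per-target trial counts drawn uniformly from [9, 13] (3D) and [15, 27]
(2D). A trial runs at 30 Hz: the intended velocity points from the cursor
to the goal at the base intended speed (ks mm/s, so that noiseless decoding
is self-consistent); unit rates are evaluated from the speed-augmented
tuning model r = b0 + ||v|| bs + m (v·p) at the *normalized* intended
velocity and floored at 0 Hz; with Poisson noise, spike counts are drawn
per bin, smoothed over the last five bins, decoded, and integrated; the
trial succeeds when the cursor center comes within 16 mm of the target
center (sum of the two radii; the 0–100 ms hold period is omitted as
negligible for mean rates) and fails at the 2 s reach cap. Per-trial mean
rates over presentation→acquisition are stored.

Default population: uniform-sphere preferred directions, b0 ~ U(8, 25) Hz,
m ~ U(3, 12) Hz. The elevation-biased option draws azimuth uniformly and
elevation normally around a bias angle with SD 1/√concentration radians.

Mechanisms (applied in the 2D context only):

* **null** — identical tuning in both contexts.
* **speed_gain** — intended speed multiplied by g (default 1.2): every
  unit's planar range scales by exactly g.
* **reaiming** — a per-target aim table replaces the displayed target as
  the goal. Two canonical tables are provided: `elevated_aim_table(ε)`
  tilts every aim point ε above the plane (a subject uniformly "pushing"
  the cursor upward; it offsets rates by ±m sin ε sin φ but scales all
  planar ranges symmetrically), and `push_aim_table(ε, az0)` tilts the aim
  for a target at azimuth a by ε·cos(a − az0) — up on the population's
  preferred side, down opposite — which is the geometry that produces
  *mirrored* range changes (up-PD units gain range, down-PD units lose it).
* **dra** — the planar directional term m (d_xy·p_xy) is interpolated with
  completeness weight α toward the rescaled term m (d_xy·p_xy)/||p_xy||, so
  α = 0 reproduces unadapted tuning and α = 1 gives a planar modulation
  depth of the full m. Units with exactly vertical PDs emit baseline under
  dra and are flagged with a warning. An optional exponential onset
  multiplies α by 1 − exp(−j/τ) over the first trials j of the 2D block
  (τ in trials, default 5 when enabled; instantaneous otherwise).

**Open-loop fast path.** `loop="open"` draws one whole-trial Poisson count
per unit at the intended-direction rate, with the trial duration set to the
noiseless closed-loop reach time. Under the simulator's constant
straight-line intent this is distribution-identical per trial for the
trial-mean-rate analyses, and it is used where many hundreds of sessions
are needed. It is *not* equivalent for variance-sensitive calibration
questions: the closed loop adds within-trial direction wander whose extra
rate variance turns out to matter for the type-I behavior of the range
contrast (see below), so the calibration and completeness-recovery
batteries run the closed loop.

## Range analysis

Trial- and time-averaged rates f(nD, d) are computed per context and target
from successful trials only. Planar ranges are max − min of f over the 8
common targets; full ranges over a context's entire target set. Units
missing from a context are dropped with a logged warning. The completeness
metric (ρ2D − ρ3D)/(ρ3D_full − ρ3D) is summarized over units with
|elevation| > 30° and denominator > 2 Hz (both thresholds configurable);
the summary SE uses the included-unit count.

**Discretization caveat.** With the discrete target geometry, ρ3D_full =
2m·max_d(d·p) and the planar ranges carry the azimuth-discretization factor
max over 8 azimuths of cos(azimuth offset). The ratio ρ3D/ρ2D = cos φ is
exact under full dra (both planar ranges share the same azimuth factor,
which cancels), but the completeness metric at α = 1 equals 1 only when the
PD aligns with the target grid; across random PDs it spreads roughly ±0.1
around 1. Only in the continuum idealization (ranges evaluated over all
directions from the fitted models) does the metric recover α exactly per
unit.

## Statistics

The stats module is self-contained, with conventions matched to how the
analyses report their statistics: W is the positive-rank sum after
discarding zero differences (mid-ranks for ties; exact two-sided p by full
sign-assignment enumeration for n ≤ 15, tie-corrected normal approximation
with continuity correction beyond), S the count of positive differences
(exact binomial), U the mid-rank Mann–Whitney statistic of the first sample
(exact by enumeration of group assignments while C(n, nx) ≤ 2·10⁵). The
Moore paired-angle test ranks the per-pair difference vectors
(cos a − cos b, sin a − sin b) by magnitude and forms the rank-weighted
resultant R′ = |Σ rank_j (cos θ_j, sin θ_j)| / n^{3/2}; because published
critical-value tables are coarse, the p-value is a seeded
rotation-permutation estimate (each difference vector rotated by an
independent uniform angle; 10⁴ resamples by default), with the tabulated
bound reported alongside. Note that this statistic detects a *common
direction* of paired change: a uniform rotation applied to uniformly
distributed angles produces uniformly distributed difference vectors and is
correctly not detected; rotation of concentrated angles is. Weighted linear
regression minimizes Σ w(y − a − bx)² in closed form, with an F-test of the
slope against the weighted constant model.

## Mechanism discrimination

* **Dose–response**: ρ3D/ρ2D regressed on |φ| or cos φ. Default regression
  weights are delta-method inverse variances of the ratio, built from the
  per-target rate standard errors at the extreme targets — this
  down-weights small, noisy denominators; unit weights are available.
* **Optimal re-aiming**: per-unit log-linear fits on the 3D block feed the
  one-step objective ‖85·d − Δt·ks·(nD/N) Σ p_i (r_ll,i(d*) − b0_i)/m_i‖
  minimized over d* on the unit sphere (coarse 5° grid scan, then ≥ 8
  Nelder-Mead refinements from well-separated best cells; ties broken
  toward the target). The PVA form of the objective is used regardless of
  the session's decoder family. Because the 2D cursor cannot move in depth,
  the z-component of the one-step displacement is zeroed inside the
  objective by default (`zero_z=False` keeps the unconstrained form).
  Predicted re-aiming ranges over the aim points versus model planar ranges
  over the common targets give per-unit predicted signs, tabulated against
  observed signs in a 2×2 contingency table.
* **Mirrored pairs**: pairs with |Δazimuth| ≤ 15° and opposite-sign
  elevations (|φ| ≥ 10°); per-trial rates at the shared planar target, the
  3D targets immediately above/below it, and the matching 2D target are
  compared with Mann–Whitney tests.
* **Classifier** (`classify_mechanism`): decision rules over three
  statistics that are mutually exclusive up to noise — (1) re-aiming when
  up-PD and down-PD units change their preferred-target rates in opposite
  directions (depth-normalized, Welch t, p < 0.005, opposite group means);
  (2) dra when the cos-transform dose–response slope is positive and
  significant (slope > 0.25, p < 0.01); (3) speed gain when the weighted
  mean ratio falls below 0.89; else no adaptation. The thresholds sit in
  the gaps observed on a development set of seeded sessions separate from
  the test battery's seeds. The predicted-vs-observed contingency is *not*
  used by the classifier: for azimuth-uniform populations the optimal aim
  points derived from near-linear tuning carry no systematic elevation
  (up-PD units behind the movement pull back exactly as much as those ahead
  push), so the prediction is noise-dominated there; the
  elevation-sign contrast is the robust form of the same mirrored-pair
  logic.

## Adaptation timecourse

Even/odd cross-validated planar tuning models are fit per context on
common-target trials, with trials numbered per target within their block so
the split is balanced by construction (failed trials are skipped). The
per-trial error is the population mean of |observed − predicted| / √(d_2D ·
d_3D) per unit, predictions from the opposite-parity model of each context;
the curve spans the last 60 planar-target 3D trials and the first 120 2D
trials (non-common 2D targets excluded). The normalizer is the geometric
mean of the two context dispersions, so scaling one context's dispersions
by k scales the metric by k^(−1/2) and scaling both by 1/k. The model
family is selectable: log-linear (the family that defines the dispersion
in the re-aiming analysis) or linear; the linear family is preferred for
simulator data, whose rates are exactly linear in direction — the
exponential family's systematic misfit otherwise adds an error floor that
distorts the fitted decay. The post-switch drop is fit by nonlinear least
squares to y = a + b exp(c x) (a initialized to the mean of the last 20
points, b to y(1) − a, c to −0.2 and bounded below −1e-4), with 95% Wald
intervals from the asymptotic covariance.

**Detectability limitation.** The error metric rectifies per-unit errors
before averaging, so a transient Δ much smaller than the single-trial noise
σ contributes only ≈ Δ²/(2σ²) of the floor and its apparent decay rate
doubles. At the generator's default tuning amplitudes (m ≤ 12 Hz) and
Poisson noise, the context-switch transient is of this invisible scale;
the τ-recovery battery therefore runs noiseless sessions (replicate
variability from seeded populations and trial plans), where the fitted
|1/c| recovers a generating τ = 5 trials within 30%. Recovering τ under
Poisson noise would require modulation depths several times larger relative
to the noise floor than the defaults provide.

## Study conditions used by the test batteries

* Identity checks (speed-gain 20%, dra cos-φ geometry): noiseless sessions
  with baselines drawn above the largest modulation depth (b0 ∈ [16, 25],
  m ∈ [3, 12] Hz) so the 0 Hz floor stays inactive — the identities are
  properties of the unclipped linear model.
* Separability: 60 closed-loop Poisson sessions, 26 units, paper-scale
  trial counts; 20 each of dra (α = 1), speed gain (g = 1.2), and
  re-aiming. Re-aiming sessions use an elevation-biased population (bias
  +15°, concentration 0.5, i.e. ≈ 40% of units below the plane — matching
  the roughly balanced predicted-decrease proportions the re-aiming
  analysis is designed around) and the constant-elevation aim table (+30°).
* Type-I calibration: 200 closed-loop Poisson null sessions; Wilcoxon on
  planar range differences at α = 0.05. The closed loop is essential here:
  the 2D block's larger trial counts make the max−min range estimator less
  noise-inflated in 2D than 3D, a bias that the open-loop path (16%
  rejections) does not dilute but closed-loop within-trial direction
  wander does (6% rejections, within 5% ± 2%).
* Completeness recovery: α ∈ {0.25, 0.5, 0.75}, 50 closed-loop Poisson
  replicates each; the grand mean of the per-session included-unit means
  recovers α within 0.1 (measured 0.22/0.43/0.67 — the ≈ 10% shortfall is
  the noise-inflation bias of the denominator partially offset by the
  geometric factor above).
* Timecourse recovery: 50 noiseless replicates, τ = 5 trials, linear
  cross-validated models.

These batteries characterize the pipeline on data generated by its own
idealized model — cosine tuning that is exactly linear, Poisson spiking,
constant straight-line intent, instantaneous or single-exponential
adaptation. Real recordings add non-Poisson variability, tuning drift,
signal loss, and intent that deviates from straight lines; passing these
batteries shows the analysis chain is correct and calibrated under the
model, not that the model captures everything in real sessions.

## Known limitations

* The completeness metric is geometry-biased at the per-unit level (see
  the discretization caveat); population summaries are accurate to a few
  percent.
* The adaptation-timecourse metric cannot see transients far below the
  single-trial noise floor (rectification bias).
* The re-aiming *prediction* (optimal aim points from 3D fits) has little
  power for azimuth-uniform populations with near-linear tuning; its
  discriminating value comes from populations or tuning with real
  convexity/asymmetry.
* Hand-control sessions are emulated as null-mechanism sessions; no
  kinematics or biomechanics are modeled.
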