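# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `dropexplore`. Everything stated here is computed by the
package's tests or by `scripts/acceptance.py`; nothing is asserted beyond
what those runs show.

## 1. The exploration loop

**Random goal exploration** is the simplest member of the curiosity-algorithm
family: one uniformly sampled temporary goal per experiment, a forward model
fitted to the entire history, and a goal inversion to pick the next
experiment. The loop starts from zero data; the first `n_bootstrap = 10`
experiments are uniform random picks, because a local linear model in four
inputs needs at least five support points and a little spatial spread before
its inversions are meaningful. If an inversion is ever unavailable the
iteration falls back to a random pick with a logged warning, so the budget
accounting is exact: a run of budget B always contains exactly B records.

All randomness derives from a single integer run seed through named child
streams (`goal-sampling`, `bootstrap`, `environment-noise`, `optimizer`),
making every run bit-reproducible from its seed. The experiment log persists
floats as `repr` strings, so save/load round-trips are bit-exact.

### Forward model (LWR)

Gaussian kernel in raw ratio space, `w_i = exp(−‖x_i − x_q‖²/2h²)` with
default bandwidth `h = 0.1` — chosen so that a local neighborhood
(roughly 5–10 % of a 1000-point exploration log) carries non-negligible
weight. Each observation dimension is fitted independently by weighted
ridge regression on query-centered inputs (intercept unpenalized,
`λ = 1e-6` for conditioning), and the fit is evaluated at the query, i.e.
the intercept. When the Kish effective sample size of the weights falls
below `min_points = 5`, the prediction falls back to the kernel-weighted
mean; if the kernel underflows entirely, to the nearest stored observation.
Predictions are clipped to be non-negative, as both observables are.

Two consequences worth knowing: with `h → ∞` the predictor reduces to a
global ridge fit, and with `h → 0` at a stored point it reduces to that
record's observation — both are tested against closed-form oracles.

### Goal inversion (CMA-ES)

The inversion cost is the squared distance, in normalized observation
space, between the LWR prediction and the goal. The search runs a compact
(mu/mu_w, lambda) CMA-ES (standard rank-one + rank-mu covariance update,
cumulative step-size adaptation; population 8 in dimension 4) over the box
`[0,1]^4`, clipping candidates to the box and renormalizing onto the
simplex inside the cost function. Defaults: `sigma0 = 0.3`,
`max_evaluations = 240`, no restarts — enough to land within `1e-3` of the
exhaustive simplex-lattice minimum on the test problems while keeping a
300-experiment run around 20 s on one CPU.

A fixed 4-level-per-axis audit grid (levels 0, 1/3, 2/3, 1, deduplicated on
the simplex) is evaluated first; its argmin seeds the search and floors the
result, so the achieved cost never exceeds the grid's best. Ties are broken
toward the lexicographically smallest ratio vector everywhere (search and
oracle), which makes results on symmetric problems deterministic. Because
the generation stream of a run is a prefix of any longer run, increasing
`max_evaluations` (without restarts) can only improve the achieved cost.

One deliberate deviation from an idealized invariant: the CA's
goal-reaching error does not decrease monotonically block-by-block — on an
easy environment the model converges within the first ~50 experiments and
the residual is optimizer-floor noise (~0.01 in goal space). The tests
therefore compare early vs late blocks with a small floor allowance,
restricted to goals inside the environment's reachable image.

## 2. The synthetic droplet environment

The simulator is a test harness with exact ground truth, not a fluid-dynamics
model. It emulates the qualitative features that matter to the exploration
and analysis code:

* **Rare, localized activity.** Noise-free mean speed is a sum of
  `n_active_modes = 3` squared-exponential bumps (amplitudes 6–9 mm/s,
  width 0.10 in simplex Euclidean distance) centered at fixed random
  locations on the simplex. Under uniform sampling fewer than ~7 % of
  formulations exceed 3 mm/s at 27 °C — high activity is rare, as in the
  real system. Droplet count uses a distinct mode map (amplitudes −2…6)
  around the baseline of 4 droplets.
* **A sharp temperature regime.** All activity is gated by a logistic in
  temperature (midpoint 24.8 °C, steepness 1.5 /°C), reproducing a
  switch-like contrast between 22.6 °C and 27 °C.
* **A fixed landscape.** Mode centers/amplitudes derive from a
  `landscape_seed` separate from the run seed, so different exploration
  seeds probe the *same* simulated chemistry, as repeats on a physical
  system would.

Observation noise (SD 0.3 mm/s speed, 0.5 count) is by default a pure
function of (formulation, seed, temperature) so `simulate_experiment` is
deterministic; the closed-loop runner instead passes its own
`environment-noise` stream so successive experiments get independent noise
while the run remains reproducible.

### Six-phase trajectories

Long (15-min) experiments follow a shared speed envelope constructed
**boundary-first**: the five transition times between the six motion phases
(initiation, fluctuation, irregular, deceleration, continuous, saturation)
are linear in temperature,

    t_j(T) = base_j + slope_j (T − 25 °C),
    base  = (40, 110, 180, 330, 480) s,
    slope = (−2, −4, −6, −8, −10) s/°C,

and the acceleration profile is a continuous piecewise-linear curve
(triangle lobes) whose characteristic points — 10 %-of-maximum rise, first
maximum, zero crossings, minimum — fall *exactly* on those times. The speed
(its integral) is piecewise quadratic with peaks of
`V1(T) = 3.0 + 0.20 (T − 20)` and `V2(T) = 2.5 + 0.25 (T − 20)` mm/s exactly at
boundaries 3 and 5, a trough at 30 % of the lower peak, and a 180-s
saturation ramp back to rest — so hotter experiments peak earlier and
faster, with analytically known ground truth for every test.

Droplets start in a Y pattern (center + three 4-mm spokes in a 16-mm
arena), move at the envelope speed with phase-dependent heading diffusion
(large turning variance in the fluctuation/irregular phases, nearly
persistent heading in the continuous phase), and reflect off the arena wall
with the step split at the crossing, so path length is conserved. With zero
angular noise the cumulative path length equals the envelope integral to
quadrature accuracy.

**What the generator does not emulate:** no droplet–droplet interaction, no
division/fusion at the trajectory level (the tracking fixture generator
scripts those explicitly), no dissolution chemistry, no formulation
dependence of the long-run motion program (the phase campaign models a
single focus recipe), and no claim that the activity landscape resembles
the real one. Passing tests therefore demonstrate that the *algorithms*
recover what this family of dynamics encodes — not quantitative fidelity to
any physical droplet system.

## 3. Droplet tracking

Frames are thresholded with Otsu's method computed on the first frame and
held fixed (overridable); detections are connected dark components inside
the arena circle with area ≥ 4 px², located by darkness-weighted centroids
(sub-pixel on anti-aliased disks; < 0.01 px on the fixtures). Linking is
greedy nearest-neighbor in ascending distance with ties broken toward the
lowest track id; the default linking radius corresponds to 12 mm/s at
20 fps — comfortably above the ~10 mm/s maximum the system produces.
Unmatched detections open new tracks (splits). Unmatched tracks close as
`exited` if last seen within the outer 15 % of the arena radius, `fused` if
their last position lies within the linking radius of another track's
match, else `ended`.

Speeds are computed from centroid displacements in mm at the frame rate;
per-track profiles use a centered 2-s moving average truncated at the ends.
The experiment summary time-averages the per-frame mean speed and the
per-frame track count. On noise-free fixtures the pipeline recovers a
2.0 mm/s circular-motion speed within 0.1 % and droplet counts exactly.

## 4. Analysis

**Coverage** maps observations to the unit square (default bounds 0–10 mm/s
and 0–10 droplets, clipped) and bins them on a 20×20 grid. Because the true
reachable set is unknown, "percent of observable space" is normalized by
the pooled occupied-cell union of the runs being compared; the per-prefix
curve is non-decreasing by construction and the cell sets match a
brute-force enumeration exactly.

**Active experiments** use a strict `> 3 mm/s` threshold. Group comparisons
use the standard two-sided Welch test (scipy, with Welch–Satterthwaite df),
degenerate equal-constant groups returning p = 1 by convention.

**Temperature inference** is distance-weighted k-NN (k = min(5, n),
scikit-learn) in normalized observation space — chosen precisely because it
adds no modeling assumptions. On synthetic data for an active recipe
(200 train / 100 test, 20–30 °C, default noise) it recovers temperature
with ≈ −0.07 ± 0.84 °C error; exact-match queries return the training
temperature.

**Phase pipeline.** Per-droplet speeds get a 1-s median prefilter (removing
single-sample glitches such as a droplet folding back off the wall within
one frame) before droplet- and experiment-averaging and 2-s smoothing;
acceleration is the centered difference of the smoothed speed. Transitions
are characteristic points of the acceleration: threshold rise (10 % of the
first maximum), first maximum, then three sign changes. For robustness the
detector re-smooths the acceleration over 6 s, accepts a sign change only
if it persists (> 70 % of the following 20 s beyond a dead band of 8 % of
the acceleration scale), and refines each located feature with a
broken-stick least-squares fit (two line segments with a scanned break;
±30–35 s window) — the statistically right model for a piecewise-linear
profile, unbiased where local line or parabola fits inherit a slope-asymmetry
bias. Missing features are reported absent, never fabricated: a monotone
profile yields no transitions, a single-peak profile lacks the later ones.

Experiments are binned in 1 °C intervals and profiles averaged *within* a
bin before detection (averaged curves are far less noisy than single
experiments); each transition observed in ≥ 2 bins is fitted linearly
against bin-center temperature. The resulting diagram enforces the ordering
invariant (boundary times strictly increasing P1→P6 across its temperature
range) and classifies any in-range (time, temperature) point into one of
the six phases. On a 59–60 experiment campaign over 20–30 °C the pipeline
recovers all five transitions within 1.5 s per bin and all slopes within
a few percent.

## 5. Problem sizes and numerical choices

* Benchmark scale: budget 300 per run, 5 matched seed pairs, hot (27.0 °C)
  vs cold (22.6 °C) — a desk-scale rendering of the original
  1000-experiment, 3-repeat design that preserves all three directional
  contrasts (CA > random coverage; CA > random active count when hot;
  CA hot−cold contrast ≫ random's).
* Phase campaign: 59 experiments (acceptance) / 60 (tests), 900 s at
  dt = 0.25 s, bin width 1 °C.
* Tolerances used by the tests: LWR vs closed form < 1e-6 on noise-free
  linear data; inversion ≤ lattice oracle + 1e-3; Welch vs formula 1e-10;
  tracking speed within 2 %; transitions within 2 s per bin; slopes within
  15 %.
* Tie-breaks: lexicographic on ratio vectors (inversion and oracle), lowest
  track id (linking). Degenerate inputs raise typed errors
  (`InvalidFormulationError`, `DatasetParseError`, `ConfigError`,
  `ModelUnavailableError`, `InvalidSamplingError`, `FixtureError`) rather
  than producing silent values.

## 6. Known limitations

* The simulator's activity landscape and envelope are constructions; their
  constants (mode widths, amplitudes, boundary slopes) were chosen once for
  qualitative plausibility, and no quantitative agreement with physical
  droplet measurements is claimed or tested.
* Coverage percentages depend on the pooled-union normalization: they are
  comparable within a compared set of runs, not across publications.
* The transition detector assumes a two-peak speed program; profiles with
  more structure would need the characteristic-point definitions extended.
* Goal inversion optimizes the model's belief, not the environment; in very
  noisy regimes the CA's advantage narrows, as it must.
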