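# Methods

This note documents the models, estimators and numerical choices behind
`dendrotrace`, in the spirit of a package's statistical reference: what
is assumed, what the tunable parameters mean, and what the synthetic
tests do and do not establish about real data.

## Granule motion model

Granule trajectories on the dendrite arc axis (soma at 0, anterograde =
increasing arc) follow a continuous-time semi-Markov switching process
over three states: paused, anterograde, retrograde.

- A granule is *ever mobile* with probability `p_mobile`; immobile
  granules hold a fixed position for the whole recording (half of them
  are placed within 1 µm of a spine when spines are supplied, so
  baseline spine occupancy exists).
- Run speeds are log-normal with direction-specific means (`v_antero`
  0.56 µm/s, `v_retro` 0.49 µm/s by default) and a common coefficient
  of variation `speed_cv` (0.3). Within a run the speed is constant, so
  with zero localization noise per-run displacement/duration equals the
  drawn speed exactly (a calibration the tests assert).
- Run lengths are exponential (`run_len_mean` 8 µm). During a run a
  pause intrudes at constant hazard `pause_rate` (0.05 s⁻¹); pause
  durations are exponential (`pause_dur_mean` 10 s). After a completed
  run the granule reverses with probability `p_reverse` (0.3),
  otherwise pauses and resumes in the same direction — this is what
  produces interrupted (pause between unidirectional runs) and
  multidirectional tracks. `p_reverse` is a model parameter the
  underlying imaging literature describes only phenomenologically
  ("sushi-belt"-style bidirectional trafficking); 0.3 makes all five
  motility classes populated at the default recording length.
- When a mobile granule reaches a spine whose radius (2.5 µm) contains
  another granule, it reverses there with `p_reverse_at_spine` (0.5),
  emulating occupancy-dependent turnaround. One such check is made per
  run against the nearest occupied spine ahead.
- Trajectories are sampled at `frame_interval` (1 s; recordings default
  to 300 s, i.e. 5 min at 1 fps), corrupted with Gaussian localization
  noise (`loc_noise_sd` 0.05 µm) and clipped to [0, dendrite length].
  A granule reaching either end of the imaged region holds there for
  the remainder (it has left the analyzable segment).

Defaults are the control-condition values of the experimental paradigm
the package quantifies; a knockdown-like regime is expressed by lowering
`p_mobile` (0.119), and a coat-protein-alone control by `p_mobile`
around 0.05.

What the generator does **not** emulate: photobleaching, intensity
fluctuation of granules, diffusive (sub-resolution) wobble beyond
Gaussian noise, dendrite curvature in the motion model (motion is 1-D
in arc space), granule merging/splitting, and any coupling between
stimulation and granule kinetics. Passing recovery tests therefore
demonstrate estimator correctness under the stated model, not
robustness to every artifact of real microscopy.

## Rendering, detection, linking

Spots are rendered as 2-D Gaussians (sd `psf_sigma`, default 0.25 µm;
pixel 0.16 µm — plausible spinning-disc values, configurable because
the source acquisitions do not pin them) with expected `photon_scale`
photons each, Poisson noise on signal + background and additive
Gaussian read noise.

Detection is Laplacian-of-Gaussian filtering at the PSF scale, local
maxima, an SNR gate against a robust background (median + 1.4826·MAD —
scale-free across photon budgets), and intensity-weighted centroid
refinement in a ±3σ window. Linking is per-frame-pair Hungarian
assignment gated at `max_disp_per_frame` (1.2 µm — covers 0.56 µm/s at
1 fps with margin) with gap closing up to `max_gap` (2 frames); ties
are broken toward the lower track id, making linking deterministic.
Tracks are projected orthogonally onto the dendrite polyline;
detections beyond the corridor half-width (1.5 µm) are off-dendrite and
excluded. Kymographs take the maximum intensity over the corridor at
each arc bin.

## Run segmentation and motility classes

Inter-frame steps are labeled paused when |Δs/Δt| < `pause_max_speed`
(0.1 µm/s), otherwise by sign; maximal same-label groups form segments,
and mobile segments with net displacement below `run_min_disp` (1 µm)
are demoted to pauses — this absorbs localization jitter (at 0.05 µm
noise, spurious "moving" steps have ~0.1–0.2 µm extent and are always
demoted). Classification: a track is stationary when its summed
mobile-run displacement is below `mobility_min_disp` (2 µm over the
recording; the quantity "mobile" is never numerically defined in the
source experiments, and 2 µm ≈ twice the linking gate rejects jitter),
multidirectional when mobile runs exist in both directions, interrupted
when unidirectional runs are separated by at least one pause (we
require ≥ 1 pause; the source material does not state a count), and
anterograde/retrograde otherwise.

### Velocity estimation

The run's defining velocity is signed displacement over duration. At
1 fps, however, a run's first and last frame-to-frame steps usually
span the state switch, so the recorded duration overcounts the true one
by up to two frame intervals and the endpoint estimator is biased low
by ~6 % at the default run length. Cohort summaries therefore estimate
per-run speed as the mean of *interior* step velocities (exact for
noiseless piecewise-linear motion, unbiased under symmetric noise).
Runs with only two steps have no interior step; for them the endpoint
estimate is corrected by the expected boundary overcount derived under
a uniform switch-phase assumption: a boundary step is kept in the run
only when its speed clears `pause_max_speed`, i.e. when its covered
fraction α ≥ β = pause_max_speed/v, so E[overcount per boundary] =
(1 − β)²/2 frame intervals; two fixed-point iterations resolve the
v-dependence. Single-step runs fall back to the raw endpoint value.
Measured over 30 independent cohorts of 200 granules at 0.05 µm noise,
the resulting per-direction means are unbiased to < 0.1 % — well within
the 3 % the recovery tests demand. Excluding short runs instead would
bias the mean low, because short *duration* selects for high speed.

## Spine interaction

All spine logic runs in arc space against PSD95 punctum positions
(punctum segmentation from images is out of scope).

- *docked*: within the 2.5 µm radius for the entire recording.
- *docking*: enters the radius and resides there — either through the
  end of the recording, or with a paused spell ≥ `residence_min` (10 s;
  ten frames at 1 fps separates residence from transit — the source
  definitions give no residency time) fully inside the radius. A slow
  pass-through that merely spends 10 s inside does **not** count,
  because residence is required to be stationary.
- *undocking*: begins inside, stationary for ≥ `residence_min`, then
  exits; the event is logged at the first frame beyond the radius.
- *direction change*: a reversal of run direction at a frame inside the
  radius.

"Reversal at an occupied spine" counts a direction-change event as
occupied when at least one *other* granule is within the radius at the
event time (concurrent occupancy, the natural reading of "already
occupied"). The reported fraction depends strongly on granule density:
with many resident granules most spines are occupied most of the time,
so the fraction should be compared across conditions, not read as an
absolute.

Recruitment around a stimulated spine reports (i) the change in granule
count within ±5 µm from just before stimulation to +5 min after and
(ii) the number of granules within ±25 µm whose net displacement over
the post window reduces distance to the spine by at least `run_min_disp`.
Both half-widths and the 5-min window are configurable.

## Structural plasticity

Volume traces are percent-of-baseline, with the first uncaging pulse at
t = 0 and the baseline window normalized to 100 %. The generator rises
linearly to 100 + amp_transient at +90 s and relaxes exponentially
(τ = 120 s) to the 100 + amp_sustained plateau. Read-outs: transient =
value at the sample nearest +1.5 min (nearest-sample, not
interpolation, matching slow-rate sampling conventions); sustained =
mean over +28.5 to +32.5 min, with the +30.5 min single-sample variant
reported alongside (both appear in the source literature, so both are
computed and labeled); fast-window = mean over 88–92 s for fast-rate
traces; responsive ⇔ peak volume increase within (0, +5 min] ≥ 10 %.
The volume proxy is integrated spine fluorescence by convention; the
package takes traces as input and does not segment spines.

## FLIM

Photon arrivals are the two-exponential mixture
f·Exp(τ_bound) + (1 − f)·Exp(τ_free), binned over a 25 ns range
(500 × 0.05 ns). Mean lifetime is the count-weighted mean of bin
centers minus t₀; with the default range, truncation bias is < 10⁻⁴ ns
for τ ≤ 2.6 ns. The mixture weight is fitted by multinomial maximum
likelihood over bins with both lifetimes fixed (defaults τ_free 2.6 ns,
τ_bound 1.1 ns — representative of green-donor kinase sensors and
configurable; the headline experiments print no numeric lifetimes, so
this module is validated by parameter recovery only). The instrument
response is treated as a delta function with a t₀ offset: a documented
simplification — real TCSPC data require IRF deconvolution, which is
out of scope.

## Morphometry and coverage

Sholl intersections are exact segment–circle intersection counts
(quadratic roots strictly inside the segment; tangencies excluded by
strict inequality), with the soma at the root node's coordinates. The
synthetic skeleton grows tips outward with small angular jitter but
strictly increasing radius, so every circle below a tip's extent is
crossed exactly once per tip; the circle exactly at the clipped tip
radius is a tangency and numerically ambiguous, and tests avoid it.
Spine typing (thin/mushroom/stubby/filopodium) is taken as annotation;
density is spines per 100 µm.

The fragment caller thresholds coverage at `peak_frac_of_max` (0.5),
merges above-threshold runs across gaps ≤ 10 nt, drops runs < 50 nt,
and ranks by mean depth (deepest = major). Parameters are ours — the
source analysis reports segments but no caller settings. Coordinates
are 1-based inclusive; segment length is end − start + 1 (the 898–1130
interval is thus 233 nt). A perfectly flat profile returns one
full-length segment, since every position attains the maximum; this
degenerate behavior is pinned by a test. BED output converts to
0-based half-open.

## Statistics and the pipeline

Group comparisons are off-the-shelf: two-tailed Student's t,
Mann-Whitney U, one-/two-way ANOVA with Tukey's post-hoc (scipy /
statsmodels); no correction beyond Tukey is applied. The full pipeline
(`report.run_pipeline`) chains simulation → transport → spine →
plasticity → FLIM → Sholl → fragment stages from one seed, writes a
JSON summary stamped with a configuration hash, and is bit-reproducible
under a fixed seed. Every generator draws from a single
`numpy.random.Generator` seeded per call; no global random state is
used.

## Problem sizes

Recovery tests and the acceptance script use cohorts of 200–300
granules over 300 s recordings, 12–15 spine traces, 10⁴–10⁶-photon
histograms, and skeletons of a few hundred nodes — sizes matched to the
per-neuron and per-condition sample sizes of the experimental paradigm,
at which every check completes in seconds to a couple of minutes on one
core. Cohort-level quantities reported from a single simulated cohort
scatter with the corresponding binomial/SEM width around the generator
setting; tests therefore compare against explicit confidence intervals
rather than point equality.

## Known limitations

- Detection/linking parameters were chosen for sparse scenes (≤ ~10
  granules per 100 µm dendrite in view); dense scenes would need a
  motion-model-aware linker.
- The motion model has no mechanistic motor switching; it reproduces
  summary statistics, not microscopic kinetics.
- FLIM ignores the IRF and background photons.
- Two-way ANOVA accepts only the "levelA|levelB" cell-label encoding.
- The kymograph builder projects every pixel onto the path with a
  Python loop; it is meant for the ~100 µm × 5-min stacks of this
  workflow, not large volumes.
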