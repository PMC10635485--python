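# Methods

## Virtual beamline

**Specimens.** Three phantom classes emulate the specimen geometries a
soft X-ray STXM + low-energy-XRF instrument meets. `filaments`: a few
angle-random-walk curves, dilated and smoothed, on an empty support
window (support fraction typically 0.2–0.4); `leaf`: one connected
irregular blob with internal holes, built by thresholding a smoothed
Gaussian random field (standardized after smoothing, so thresholds are
in units of the field's own spread), keeping the largest connected
component before and after hole carving; `stone`: an effectively opaque
matrix (optical depth 20, transmission ~2·10⁻⁹) with hole regions of
zero emission and a trace element at low rate (default Na at 2 counts/s
vs Si at 60 counts/s). All grids share one shape; transmission is
`exp(−μ·thickness)` with μ = 1 per thickness unit; the differential
phase contrast grids are the central-difference gradient of thickness
(one-sided at the boundary); a pixel is "sample" where thickness
exceeds 0.05. Element abundance profiles are declared per region
(`support`, `body`, `inclusions`, `trace`) with rates in counts/s at
nominal flux; sample-bound elements are exactly zero outside a
one-pixel halo of the support mask.

**Beam.** Ring current decays exponentially from a 300 mA reference
with characteristic time `decay_time` and is restored instantaneously
every `topup_period` (sawtooth). Positional drift is a slow biperiodic
wander (periods 900 s and 900/1.618 s, random phases from the beam
seed) of amplitude `position_amp` micrometres; it enters the four BPM
blade currents as `gain_k · f(t) · I_ring(t) · (1 + c·proj_k(drift))`
with opposite signs on opposing blades (so the blade sum is exactly
proportional to delivered intensity times ring current), and couples
weakly into delivered flux through `intensity_coupling`. Motor drift is
linear in time and displaces the actually illuminated pixel — the
failure mode that static masks suffer from and dynamic triggers do not.
No quantitative drift amplitudes are claimed to be instrument-accurate;
the defaults are chosen to visibly reproduce the qualitative artifacts
(banding under decay, position-coupled blade imbalance) and are all
config-exposed.

**Measurement.** Transmitted signal = `flux(t) · T(pixel) · dwell` plus
Gaussian readout noise of configurable sigma; XRF counts per element
are Poisson with mean `rate · dwell · flux(t)/nominal_flux`. A zero
dwell means the modality is simply not acquired. XRF is simulated as
per-element ROI count streams, not full spectra: every trigger decision
in the package operates on an ROI count, so channel-level counts are
the minimal sufficient statistic. A Gaussian-peaks spectrum synthesizer
is provided for rendering average spectra only and feeds no decision
logic.

**Coordinates.** Pixels are 0-based row-major; the physical position of
pixel (i, j) is `origin + (j·step, i·step)` micrometres. This makes the
CSV motor-position export a direct affine map of the indices.

## Scan engine and time accounting

Pixels are visited in row-major unidirectional order by default
(serpentine available); unidirectional keeps the floating-window stream
interpretable across rows. At each pixel the fast modality is acquired
first (STXM, or the short XRF probe for XRF-only strategies), the
strategy is consulted, and the long XRF dwell spent only on a positive
decision. STXM is acquired everywhere by default, since it costs
milliseconds and gives a complete transmission image for presentation;
a flag restricts it to triggered pixels. Every charge (move overhead,
each dwell) is added to the running clock in order, and the per-pixel
dwell logs allow the total to be recomputed bit-exactly — adding a zero
dwell is an exact no-op in IEEE arithmetic, so the recomputation can be
unconditional.

The engine derives three independent RNG streams (STXM noise, fast XRF,
long XRF) from the one scan seed. Because decisions only consume the
fast stream, sweeping the threshold leaves the compared values
untouched, which makes "acquisition fraction is non-increasing in
threshold" an exact property rather than a statistical one.

`t_move` defaults to 0 but is config-exposed: a real 490,000-pixel scan
at ~1.005 s/px of dwell that takes 164 h implies roughly 0.2 s/px of
unaccounted overhead, so both a proportional and an overhead-inclusive
accounting are available. `SavingsReport.from_durations` implements the
proportional reading (saving = 1 − t_cs/t_full, coverage inferred from
the same ratio); `summarize_savings` uses the overhead-inclusive
closed form against the record's own elapsed time. For variable-dwell
XRF-only scans the savings can be quoted as either "reduced BY" or
"reduced TO" a fraction; both conventions are derivable from the report
fields, and none is asserted as the canonical one.

## Trigger strategies

All comparisons are strictly greater-than ("higher than the
threshold"): a value exactly equal to the threshold does not trigger.

**Static mask.** Spare points are drawn once per scan — uniformly
without replacement from the outside-mask pixels, `round(f·n_outside)`
of them, from the strategy seed — matching a workflow where positions
are precomputed into a path file, not re-drawn per row.

**Absorption threshold.** "Absorption" is defined as (reference
flat-field signal − normalized transmitted signal), with the flat-field
reference being the noiseless open-beam intensity at reference ring
current (`nominal_flux · t_stxm`). This convention is documented and
tested rather than inherited: the quantity compared is monotone
decreasing in transmitted intensity, so support pixels (high
transmission) fall below any threshold placed between support and
sample absorption. With a subtractive (floating-window) normalizer, the
threshold applies to the deviation signal (local mean minus current
value) instead — a deviation threshold, documented as such.

**Fast-XRF threshold.** For opaque samples: every pixel pays the short
probe dwell (whose spectrum is kept), and the long dwell is added where
the ROI count strictly exceeds the threshold. `choose_fast_dwell`
returns the shortest dwell on a candidate grid for which an integer
count threshold k exists with `P(counts > k | present) ≥ sensitivity`
and `P(counts ≤ k | absent) ≥ specificity` under Poisson statistics;
since specificity is non-decreasing and sensitivity non-increasing in
k, checking the smallest k that meets specificity suffices, which is
verified against an exhaustive (dwell, k) scan. Multi-ROI "element
signature" correlation variants are out of scope; the single-ROI
threshold is the implemented reduction.

**ML oracle.** See below.

## Normalization and dynamic threshold adjustment

Methods: `ring` (multiply by reference/current ring current), `bpm`
(multiply by the blade-sum ratio; the difference signals are logged but
not used), `window` (subtract the mean of the last `N` values, `N`
defaulting to twice the pixels per row), `ring_window` (window applied
to ring-normalized values), and `window_div` (divisive variant, kept
available because a subtractive and a divisive reading of a "floating
window average normalisation" are both defensible; subtraction is
primary). Warm-up rule: the window mean is taken *before* the current
value is inserted and an empty buffer contributes 0 (or 1 for the
divisive variant), so the first pixel's output is its raw value and the
first row remains usable.

For the multiplicative methods the central contract is algebraic:
comparing the raw signal to `threshold · (I_now/I_ref)` is exactly
equivalent to comparing the ring-normalized signal to the base
threshold. Both code paths exist and are checked to give identical
decisions at every pixel of a drifting 64×64 scan. Ring normalization
cancels a noiseless pure-intensity drift to machine precision; BPM
normalization additionally cancels position-coupled intensity loss
(which ring normalization cannot see), asserted as a variance ordering
on a position-drift-only scan. Offline `normalize_image` replays the
same online state machine over the recorded diagnostics stream and is
bit-identical to the values logged during the scan.

## EasyMask I/O

Mask rasters are imported from any grayscale image, thresholded at 50%
of the intensity range (pen-drawn masks are effectively binary).
Upscaling is nearest-neighbour by pixel centre; integer scale factors
preserve coverage exactly, and non-integer factors are bounded in
coverage drift by centre-sampling rounding (checked at ≤ 2 percentage
points on 64→160). The CSV dialect
(`index,x_um,y_um,stxm,xrf,t_stxm_s,t_xrf_s`; coordinates to 3
decimals, dwells to 6; 0-based strictly increasing index) is this
package's own normative contract, with distinct parse errors for bad
header, non-monotone index, out-of-domain flags and empty files. In
HDF5 archives, non-acquired XRF pixels carry the sentinel −1
(unambiguous, since counts are non-negative); diagnostics (ring
current, 4×P blade currents, timestamps) and per-pixel decision logs
(value compared, threshold in force) are stored alongside the images so
every decision is reproducible offline from the archive alone.

## In-painting

Default method is harmonic: solve the 5-point discrete Laplace
equation on non-acquired pixels with acquired pixels as Dirichlet data,
by a sparse direct factorization (exact, so the stated residual
tolerance is met trivially). At image edges the unknowns use only
their two tangential neighbours (the ghost-cell linear-extrapolation
closure) and corners the mean of their two in-grid neighbours: every
equation remains a convex combination of neighbours, so the discrete
maximum principle holds, while linear fields are reproduced exactly
along edges. When the entire border is unknown this closure would
decouple the border ring from the data, so it falls back to the
truncated (Neumann) stencil in that configuration. Counts are
in-painted as rates (counts/dwell) and rescaled to the longest acquired
dwell, so variable-dwell scans in-paint consistently; pixels acquired
at that dwell pass through bit-exactly. `nearest` breaks distance ties
toward the smallest row-major index; `idw` uses inverse-square
distance over the k = 8 nearest acquired pixels. No sparsity-regularized
reconstruction is attempted: in-painting here is presentational.

## ML trigger

`XRFOracle` is a scikit-learn-style estimator: a feed-forward ReLU
network (default two hidden layers of 32 units, LBFGS, fixed
random_state, hence deterministic) on standardized features —
transmitted intensity, the two phase-contrast gradients, ring current
and the four blade currents, optionally the replicated-padded 3×3
STXM neighbourhood — with per-element standardized rate targets.
Standardization statistics come from the training pixels only. Features
that are constant up to numerical jitter (the diagnostics of a stable
beam) have their scale floored to 1 so standardization cannot amplify
noise into extrapolation spikes. The architecture is deliberately
specified behaviorally: any pixel-wise supervised regressor passing the
predictive tests (held-out RMSE, trigger-mask IoU) is conforming, and
training masks are explicit inputs rather than a hard-coded sampling
scheme. Targets are rates, not counts, so a model trained on a coarse
fast map transfers across dwell settings. Prediction runs through the
package's own forward pass on the extracted weights, which is why a
serialized oracle (HDF5: weights, scalers, feature config, seed)
predicts bit-identically after reload. Transfer is only claimed across
samples under the same setup conditions; no uncertainty quantification
is attempted.

## Experiment configuration and seeds

A single YAML config (sections `phantom`, `beam`, `scan`, `strategy`,
`inpaint`) with defaults for everything except `scan.step`,
`scan.t_xrf`, `strategy.threshold` and the master seed; validation
errors name the offending key. Per-module seeds derive from the master
seed as `SeedSequence(master, spawn_key=(k,))` with a fixed counter per
module (phantom 0, beam 1, scan 2, strategy 3, training 4), so adding a
consumer never perturbs earlier streams; all derived seeds are reduced
below 2³¹. The resolved configuration is echoed into every HDF5 output.

## Problem sizes and what the tests show

The test suite and the acceptance script run on 24–64 pixel grids with
dwells scaled so that a simulated scan completes in milliseconds; these
sizes were chosen as the smallest at which the exactness properties
(oracle equivalence, normalization cancellation, time conservation) are
exercised exhaustively and the statistical properties (Poisson trigger
rates, spare-point fractions) have meaningful power. The phantoms
reproduce the geometric and statistical structure of real specimens —
sparse support, holes, opacity, Poisson counting, beam drift — but not
detector spectral response, optics point-spread, or spatially
correlated noise; passing tests therefore validate the decision logic,
accounting and numerics, not instrument calibration. Time-saving
figures on phantoms depend on the phantom's coverage and the dwell
ratio and are not claims about any particular specimen.
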