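# Methods

## Scope and model overview

`fmridesign` simulates single-voxel BOLD time series evoked by
*alternating* event sequences — a cue always followed by a target — and
scores candidate designs by detection power and estimation efficiency
under a prewhitened general linear model. All simulations run on the
scanner's TR grid (default TR 1.5 s, 294 scans, 441 s per run).

The pipeline per simulated design is:

1. **Sequence generation.** Onset-to-onset gaps are drawn i.i.d. from
   `Uniform(L_ISI, U_ISI)` in continuous seconds and onsets are snapped
   to the nearest TR index. Sampling in seconds and snapping afterwards
   keeps the jitter distribution exact even when integer-second ISI
   bounds are incommensurate with the 1.5 s TR; if two onsets snap to
   the same index the later one is pushed forward one TR, and an event
   pushed past the end of the run is dropped. Both the cue→target gap
   and the target→next-cue gap follow the same law (the simplest
   symmetric reading; the generator does not distinguish them). Trials
   are whole units: a trailing cue whose target does not fit is
   dropped. A requested fraction `p ∈ [0, 0.5]` of targets is replaced
   by null events — exactly `round(p·T)` of the `T` targets, chosen
   uniformly without replacement; the vacated slot keeps its timing, so
   the preceding cue's delay period simply extends to the next cue.
2. **Neural input.** Each delivered event contributes its amplitude
   (default 1.0) for one TR. Delay-period activity is modelled by
   sub-impulses at 0.66 of the event amplitude placed after the event
   according to one of six transient temporal profiles (TTPs):
   profiles 1/2 append 1 or 4 sub-impulses (attention, short lower
   bound), 3/4 are the same after a quiet delay of
   `floor(L_ISI / (2·TR))` TR steps (attention, long lower bound,
   modelling late re-engagement), and 5/6 sustain 0.66 until the next
   event (working memory), 6 with the same leading delay. Sub-impulses
   truncate at the next delivered event, so maintenance never crosses
   an event boundary; sustained profiles run through null-target slots.
   The profile is selected from the (L_ISI, U_ISI) usage map with
   configurable thresholds: L is "long" above 6 s and U above 7.5 s
   (the length of profile 2's grading — a grading should fit inside the
   typical gap it serves); a bound exactly at its threshold counts as
   short.
3. **BOLD forward model.** The canonical double-gamma HRF (gamma-density
   lobes with delays 6 s and 16 s, unit dispersions, undershoot ratio
   6:1, peak-normalized, 30 s support) is convolved with the summed
   neural input, `x = h ⋆ u`, and passed through the second-order
   Volterra polynomial `y = f₀ + f₁x + f₂x²` with `f₀ = 0`, `f₁ = 1`,
   `f₂ = −0.050`. The separable second-order kernel `h(τ₁)h(τ₂)`
   collapses the double convolution integral into this square of the
   linear response.
4. **Noise.** Four independent components: low-frequency drift (random
   cosine basis below 1/128 Hz), stationary AR(1) (ρ = 0.4, 100-sample
   burn-in), sinusoids at physiological frequencies (respiratory 0.2 Hz;
   cardiac 1.17 Hz, explicitly aliased onto the 1/1.5 Hz sampling grid
   to 0.163 Hz) and white noise, with component standard deviations
   1 : 1 : (0.5, 0.5) : 1. Only the ratios matter: before addition the
   summed noise is rescaled. In the landscape pipeline the noise level
   is fixed in *absolute response units* — sd(noise) = 1/SNR with one
   unit being the peak of an isolated unit-event response, SNR = 1 by
   default — so every design on a landscape receives statistically
   identical noise, the way a single measured noise template would be
   reused across simulations. (Scaling noise per-design to each
   signal's own sd, also available in `combine_signal_noise`, lets
   near-saturated, low-variance signals receive near-zero noise and
   distorts cross-design comparison.) Externally estimated parameters
   can be imported from YAML.
5. **Optimality.** Detection power uses `X = [1, h⋆cue, h⋆target]` and
   the differential contrast `c = e_cue − e_target`; estimation
   efficiency uses the FIR matrix (20 shifted indicator columns per
   event type, the 30 s HRF support at TR 1.5 s) with the contrast
   spanning the cue's lags. Both are reciprocal-trace efficiencies of a
   two-pass prewhitened fit: OLS, AR(1) coefficient from the lag-1
   residual autocorrelation, exact bidiagonal whitening (the inverse
   Cholesky factor of the AR(1) correlation matrix), refit, then
   `1 / (σ̂² · trace(C (XᵀV̂⁻¹X)⁻¹ Cᵀ))` with `σ̂²` the whitened
   residual mean square (floored at 1e-12 so noiseless fits do not
   blow up). `scale_by_fit=False` gives the classical data-free
   efficiency (σ̂² ≡ 1) for sensitivity analysis. Degenerate designs
   (all-null event type, singular normal matrix) score 0 and are
   flagged rather than aborting a grid.

## Design choices where the design was open

* **Detection contrast.** The default is the cue−target differential
  effect. A cue-only contrast (`contrast="cue"`) is available, but with
  it the reciprocal-trace measure grows monotonically with event count
  and the optimum degenerates onto the shortest-L edge of the grid;
  the differential effect is the quantity an alternating design
  actually struggles to resolve — it collapses both when events are
  too close (collinear regressors) and too sparse (few trials),
  producing the mid-ISI detection optimum characteristic of such
  designs.
* **Quadratic coefficient calibration.** `f₂` is the saturation
  strength, in units of 1/response-unit. For a fixed-ISI train the
  relative gap between order-2 and order-1 integrated responses is
  `|f₂|·Σx²/Σx`, linear in `|f₂|`; the default is calibrated
  (`scripts/calibrate_volterra.py`) so that this gap exceeds 10%
  exactly for ISIs of 2 s and below — the regime where BOLD saturation
  is empirically important — with the 10% crossing placed at the
  geometric mean of the 2 s and 3 s gap ratios for symmetric margin.
  A consequence worth knowing: at this strength the order-2 integrated
  response still *grows* as the ISI shrinks below 2 s (sub-linearly);
  making it flatten outright would need `|f₂| ≳ 0.16`, at which point
  the nonlinear term would exceed 10% of the response at every ISI up
  to 10 s. A pure quadratic cannot do both; the package prioritizes
  the calibrated 2 s onset of "important" nonlinearity.
* **Per-cell seeding.** Every (cell, replicate) evaluation derives its
  generator from `SeedSequence([master, axis1·1000, axis2·1000, rep])`.
  Any subgrid, single cell or single replicate is therefore exactly
  reproducible in isolation, and the partial-trial sweep keys its seeds
  by (L_ISI, U_ISI) only, so its zero-fraction row is bit-identical to
  the matching ISI-landscape cells.
* **Grading scope.** Cues and targets are graded identically by the
  selected profile (configurable in `build_neural_input` by passing a
  profile only where wanted); the delay-period literature motivates
  grading after cues, but nothing in the alternating structure forbids
  post-target maintenance, and the symmetric choice needs no extra
  parameter.

## Simulations

`run_simulation1` sweeps every `(L_ISI, U_ISI)` pair from 1 to 20 s
(step 1, cells with L > U masked), 100 freshly generated sequences per
cell, and reports mean detection power and estimation efficiency per
cell — about one minute on a single CPU for the 210-cell attention
grid. `run_simulation2` sweeps the null-target proportion 0–0.5
(step 0.1) against `U_ISI` 2–20 s (step 2) at `L_ISI` = 2 s, attention
profiles only. Landscapes export losslessly to long-format CSV and
render as heatmaps; raw values are in arbitrary units (1/variance of a
contrast estimate), so only locations of optima and orderings are
meaningful across configurations.

Typical behaviour at the defaults: detection power forms a broad ridge
with both bounds in the mid-ISI range (argmax near (6, 6–7) s; the top
cells differ by fractions of a percent, so the exact argmax cell moves
within the ridge across seeds), collapses sharply for sub-2 s ISIs and
declines beyond ~16 s where trials become scarce; estimation efficiency
rises with jitter width and peaks at the lowest L and U ≈ 18–19 s;
null targets raise detection power at short ISIs (and estimation
efficiency everywhere, visibly already at 10%), with the detection
benefit fading as U grows.

## What the generator does and does not emulate

The synthetic pipeline reproduces the features that drive design
optimality at the single-voxel level: overlap and saturation of
responses, delay-period activity, temporally autocorrelated and
structured noise at a fixed level across designs. It does **not**
emulate trial-to-trial amplitude variability, head-motion spikes,
task-correlated noise, spatial covariance or multi-voxel structure,
unequal cue/target responses (supported via `amplitudes` but not part
of the tested surface), or session/run nonstationarity. Passing tests
therefore certify the *relative* geometry of the design landscapes
under this model, not absolute detectability in any particular dataset.

## Numerical notes and limitations

* Convolution runs at TR resolution (events live on the TR grid); a
  0.1 s microtime grid is available for HRF-shape checks via
  `canonical_hrf(dt=0.1)`.
* AR(1) estimates are clipped to |ρ| ≤ 0.99; the lag-1 sample
  autocorrelation of any finite series is strictly inside (−1, 1), so
  the clip is a defensive guard.
* The landscape CSV stores values as `repr(float)` and re-parses them
  with Python's `float` to guarantee bit-exact round-trips.
* The detection and efficiency landscapes are *not* negatively
  rank-correlated cell-by-cell across the full grid (both measures are
  jointly low along the short-ISI diagonal and in the sparse long-ISI
  corner; the Spearman correlation is ≈ 0). The trade-off between them
  is a statement about their *optima*, which sit in opposite regions of
  the parameter space.
* With sustained or long graded profiles and short gaps, delay activity
  fills the entire inter-event interval; the effective event amplitude
  against the maintained plateau is then 0.34 rather than 1.0, which is
  the intended physiology of maintained activity but worth remembering
  when comparing against TTP-free runs.
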