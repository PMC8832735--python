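# Methods

## The lung model and its assumptions

All simulation and identification rests on the linear single-compartment
model of passive respiratory mechanics,

    P_aw(t) = E_rs · V(t) + R_rs · V̇(t) + PEEP,

with airway pressure `P_aw` in cmH₂O, delivered volume `V` in L, flow `V̇`
in L/s, elastance `E_rs` in cmH₂O/L, resistance `R_rs` in cmH₂O·s/L and the
ventilator-applied end-expiratory pressure PEEP in cmH₂O.  The model assumes
a passive patient (no respiratory muscle effort), linear elastance and
resistance over the breath, and negligible intrinsic PEEP.  Breaths that
violate the passivity assumption (asynchrony, effort) are detected by their
poor model fit and excluded rather than modelled.  All internal units are
L, L/s, s and cmH₂O; peak flow is converted from the clinical L/min at the
interface, tidal volume from mL/kg using the patient weight as given.

## Waveform conventions

Volume-controlled inspiration is synthesised from the set values:

* **square**: constant flow `V̇max` for `T_flow = V_T / V̇max`;
* **ramp**: descending ramp from `V̇max` to zero over
  `T_flow = 2·V_T / V̇max`, so the set peak flow and the set tidal volume
  are both honoured (standard "descending ramp" semantics; the terminal
  flow of a clinical ramp is not standardised, and a nonzero terminal flow
  would change the timing-dependent counts below).

The plateau hold (`T_plat`) is counted as inspiratory time, so
`T_insp = T_flow + T_plat`, `T_exp = 60/RR − T_insp`, and the I:E ratio is
reported as `1 : T_exp/T_insp`.  A combination whose inspiration does not
fit in the breath period (`T_exp ≤ 0`) is flagged infeasible, never raised.
Expiratory flow dynamics are not modelled in the protocol engine (only the
virtual-patient generator synthesises an expiration, for the segmenter's
benefit).

Closed-form outcomes: `P_PLAT = E_rs·V_T + PEEP`, `ΔP = E_rs·V_T`; square
`P_MAX = P_PLAT + R_rs·V̇max`; ramp `P_MAX` is the maximum of the quadratic
pressure profile over {flow onset, interior stationary point
`t* = T_flow − R_rs/E_rs` when inside the flow phase, end of flow}.
Sampled waveforms (default 50 Hz, `dt = 0.02 s`, matching the 8-sample /
0.16 s persistence criteria below) agree with the closed forms to within
one sample's pressure increment; tests enforce this property.

## Breath segmentation and true-breath screening

Segmentation uses threshold-plus-persistence rules at 50 Hz: inspiration
starts where flow > 0.1 L/s and pressure > PEEP + 2 cmH₂O with positive
flow sustained over the next 8 samples; expiration starts where flow
< −0.1 L/s sustained 8 samples.  A candidate breath is kept only if its
peak inspiratory volume exceeds 40 mL, its peak inspiratory pressure
exceeds PEEP + 1 cmH₂O within inspiration, and expiration begins within
4.125 s of the inspiration onset.  The PEEP entering the onset criterion
defaults to the global pressure minimum before any PEEP is known (a safe
underestimate); streaming callers should pass the previous interval's
estimate.  Per-breath PEEP is the median pressure over the near-zero-flow
pre-inspiratory pause (0.5 s lookback), rounded to integer cmH₂O to match
clinical reporting; without a pre-inspiratory window it falls back to the
breath's pressure minimum.

True-breath screening rejects breaths with median model-fit APE > 15%,
nonpositive (or unidentifiable) elastance, or elastance outside the
5th–95th percentile of the patient's previously accepted estimates.  The
percentile window expands over all accepted breaths of that patient and
engages once 10 breaths have accrued (skipped with a warning below that).
Two guards are ours: the band is given a minimal relative half-width of
±5%, because a nearly constant accepted history (noise-free synthetic
data, highly regular ventilation) collapses the empirical band to zero
width and would reject genuine drift — real patient histories are far
wider, so the floor does not bind there.

## Identification

Integrating the model from the breath start `t₀` to each inspiratory
sample `t_i` yields one linear equation per sample,

    [ ∫ V dt ,  V_i − V_0 ] · [E_rs, R_rs]ᵀ = ∫ (P − PEEP) dt ,

assembled from the second inspiratory sample onward with trapezoidal
quadrature throughout, and solved by Lawson–Hanson nonnegative least
squares (`scipy.optimize.nnls`).  Volume is reconstructed as the running
integral of flow, so only pressure–flow data are needed.  The regression
covers inspiration only: the fit statistic is defined on inspiratory
pressure, and passive expiration adds no identifying information under this
model.  Fit quality is `APE = median |(P_sim − P_mea)/P_sim| × 100` over
inspiration, with zero-reference samples excluded.  A rank-deficient system
(e.g. zero flow) yields an invalid estimate, flagged rather than raised.
On noiseless model-generated breaths identification is an exact round trip
(the same trapezoidal rule generates and fits the data); tests require
recovery to 10⁻³ and invariance to halving `dt` to 0.1%.

## The elastance transition model

Successive interval medians form pairs (y = E_rs,N, x = E_rs,N+1); gaps in
the interval chain break pairing rather than pairing across them.  The
conditional law is estimated by kernel density estimation with one
bivariate Gaussian kernel per pair, each axis truncated to [0, ∞) and
renormalised by its remaining mass p = Φ(centre/σ):

    P(x | y) = Σᵢ wᵢ(y) · φ(x; xᵢ, σ²ₓ)/pₓᵢ ,
    wᵢ(y) ∝ φ(y; yᵢ, σ²ᵧ)/pᵧᵢ ,   Σᵢ wᵢ = 1 ,

so the conditional density integrates to one on the nonnegative axis by
construction.  Percentile forecasts invert the numeric CDF (cumulative
trapezoid over a 1000-point grid spanning [0, 1.5·max xᵢ], linear
interpolation), which makes them monotone in level by construction.  The
model is population-level — fitted on cohort transition pairs and queried
per patient.

**Bandwidth.**  The default selector maximises the leave-one-out
*conditional* log-likelihood of the training pairs over a multiplier grid
around the Silverman pilot on each axis.  Marginal rule-of-thumb bandwidths
(Silverman, Scott — both still available, as are explicit values)
systematically oversmooth a conditional density: on synthetic transitions
with a known law they widen the 5–95 band to ~99% empirical coverage
against the nominal 90%.  Since calibrated forecast bands are the model's
entire purpose, the cross-validated selector is the default; it restores
held-out coverage to ~93%/55% against nominal 90%/50% on the same data.
CV needs at least 10 pairs and falls back to Silverman below that.

## The recommendation protocol

The setting grid is the clinical VC grid: RR 6–35 breaths/min (step 1),
V_T 4–8 mL/kg (step 1), peak flow 5–150 L/min (step 5), plateau 0–2 s
(step 0.1), square and ramp — 189,000 combinations, enumerated in a fixed
Cartesian order (RR outermost, waveform innermost); all stage counts are
order-independent (tested).  PEEP is not a grid axis: it is specified by
the clinician and enters only the pressure simulation.

Elimination applies: `P_MAX < 40` and `P_PLAT < 30` cmH₂O (strict
inequalities), I:E denominator within [1, 3] inclusive, and the RR/V_T
ranges (inclusive; they coincide with the grid).  Infeasible timing
surfaces as a nonpositive I:E value and is eliminated by the I:E bound, so
disabling every threshold genuinely keeps all combinations.  Comparisons
carry a 10⁻⁹ slack so grid points landing exactly on a limit behave
deterministically.  The narrowing objective `min_dP` keeps every survivor
tying the minimum driving pressure — because ΔP = E_rs·V_T, exactly the
lowest surviving tidal-volume tier.  For the stochastic run the narrowing
uses the 95th-percentile ΔP (conservative; with ΔP linear in elastance any
percentile selects the same tier).  An empty survivor set is a valid
outcome, reported with a warning.

The stochastic variant forward-simulates each combination twice, at the
5th and 95th percentile forecast elastance, with the current resistance and
PEEP; both simulations must pass every threshold.  Pressures are monotone
in elastance, so whenever the forecast band brackets the current value the
stochastic survivor set is contained in the deterministic one (asserted on
every synthetic run).

**Boundary-sensitivity audit.**  Identified elastances are typically
reported to 0.1 cmH₂O/L; each run therefore reports how many combinations
change survival status when the input elastance moves by ±0.05 cmH₂O/L.
This bounds how far a survivor count can legitimately move under input
rounding — but note it cannot bound deviations arising from different
*timing* conventions (ramp duration, plateau attribution, I:E rounding),
which elastance does not touch.  Published per-patient counts computed
under unstated conventions may differ beyond the audit for exactly that
reason; the conventions above are fixed and tested, and the audit
contextualises exact-count comparisons.

## The virtual-patient generator

The generator defines the study conditions for everything the original
bedside recordings would otherwise provide.  Defaults: 65 kg patient,
baseline E_rs 33.8 cmH₂O/L and R_rs 9.8 cmH₂O·s/L (cohort-median adult ICU
mechanics), PEEP 10 cmH₂O, square flow at RR 15, V_T 6 mL/kg, 40 L/min,
0.3 s plateau, 50 Hz sampling.  Elastance follows a multiplicative
log-normal walk per 10-min interval (SD 0.05 — a few percent drift per
interval, matching the interval-to-interval variation seen clinically)
reflected at physiological bounds 8–73 cmH₂O/L.  Pressure carries additive
Gaussian sensor noise (SD 0.5 cmH₂O).  Asynchrony is injected per breath
with configurable probability as an effort-like negative half-sine pressure
deflection spanning most of the inspiration at 80% of the driving
amplitude — the simplest distortion guaranteed to defeat any passive
(E, R) fit and exceed the 15% APE screen.  Expiration is a passive
exponential decay rescaled to return the volume exactly to zero.

What the generator does *not* emulate: real effort waveform shapes and
partial asynchronies, ventilator valve dynamics, intrinsic PEEP, nonlinear
or volume-dependent mechanics, setting changes mid-recording, and sensor
drift.  Passing tests therefore show the pipeline is exact on data obeying
its own model and robust to the modelled noise/asynchrony — not that it is
validated on real patients.

## Problem sizes and runtime choices

The protocol engine is vectorised over the full 189,000-point grid (a run
takes milliseconds), so all recommendation tests use the full grid.
Brute-force equivalence checks use a 1,920-point reduced grid.  The cohort
comparison uses 20 virtual patients (10 to fit the transition model, 10
evaluated over 18 ten-minute intervals each), driving the protocol from
trajectory-derived interval summaries; the full
stream → segmentation → identification → summary path is exercised
end-to-end on shorter single-patient streams (and a full 3-h, 2,700-breath
stream for segmentation).  Forecast calibration uses 500 training and 200
held-out transitions.

## Known limitations

* Volume control only; pressure-controlled modes would need volume/flow
  limits instead of pressure limits.
* One narrowing objective (minimum ΔP) is built in; the stage is a single
  dispatch point and raises on unknown names rather than guessing.
* The percentile true-breath screen inherently rejects ~10% of genuinely
  clean breaths once the accepted history is long (that is what an
  empirical 5–95 band does); interval medians are insensitive to this.
* Interval PEEP extraction trusts the pre-inspiratory pause; heavy
  asynchrony within an interval can still bias it, and no guard beyond the
  median is applied.
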