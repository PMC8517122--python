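# Methods

## Model

The DILV model treats one breath's volume and pressure traces as
independent periodic signals sharing only the respiratory frequency θ
(breaths/s).  Each signal is built constructively from discrete-time
primitives:

1. a thresholded sinusoid `sin(2πθt − φ) − b` squashed through
   `½(tanh(a·x)+1)` into a soft rectangular drive.  The offset `b` sets the
   duty cycle: the drive is high on the fraction `(π − 2 arcsin b)/2π` of
   each period, so `b = 0` gives a 1:1 inspiratory:expiratory ratio and
   larger `b` shortens inspiration;
2. first-order recursive trackers `y[i] = x[i]/β + (1 − 1/β)·y[i−1]` whose
   per-sample smoothing β ≥ 1 sets the rise (inspiration) and fall
   (expiration) gradients;
3. a leaky differencer `y[i] = (y[i−1] + Δx[i])/β` that converts drive
   transitions into geometrically decaying spikes — the plateau-peak
   (dyssynchrony-like) deformation;
4. normalization, so each term's post-warm-up peak is exactly one and the
   amplitude parameters (A_v, A_p1, A_p2, A_p3) carry the physical units.

Volume: `V = A_v(fv1 + fv2)`.  Pressure: `P = fp13 + fp24 + fp33 + A_p4`
with plateau skeleton `fp13 = A_p1(fp11 + fp12)`, plateau peaks `fp24`
(amplitude A_p2; identically zero when A_p2 = 0), low-volume knee `fp33`
(amplitude A_p3; identically zero when A_p3 = 0), and PEEP A_p4.  There is
deliberately no mechanical coupling between P and V; the compliance
readout is the amplitude ratio `Cd = A_v/A_p1` (ml/cmH2O).

### Numerical conventions

* **Warm-up (burn-in).** All recursions start at 0 and are unspecified at
  the first sample, so every simulation prepends `burn_in_periods`
  (default 3) full periods, discarded before normalization and output.
  The returned trace is therefore in periodic steady state and independent
  of the initial condition.  Slowly decaying terms (β₅ close to 1, whose
  per-sample decay ratio 1/β₅ implies a time constant of β₅·dt/(β₅−1)
  seconds) need proportionally more warm-up to reach a given periodicity
  tolerance; the periodicity tests size the warm-up accordingly.
* **Normalization windows and masking.** The rise/fall terms (fv1, fv2,
  fp11, fp12) are normalized by the maximum of the *raw* recursion output
  over the post-warm-up window and then gated by the phase mask
  (inspiration: the drive `fb`; expiration: its complement `1 − fb`).
  Because both trackers sit near their maxima exactly where the drive
  switches phase, the gated sum behaves as a convex combination across the
  transition and the composed waveform peaks at its amplitude parameter
  (within 1e−3 relative) instead of overshooting; gating before taking the
  maximum was measured to overshoot the peak by up to ~8% at sharp drive
  settings.  The knee term fp33 is normalized mask-first, as its
  denominator `max[fp32(1 − (fp11+fp12))]` contains the mask; a degenerate
  (near-zero) denominator — e.g. a pulse that never overlaps the
  low-volume window — raises a named degenerate-normalization error.
* **Masking convention.** Gating the falling terms by the expiration phase
  (`1 − fb`) is the default (`mask_convention="phase"`); gating every term
  by the inspiration drive is available as `mask_convention="drive"` for
  comparison.  Only the phase convention lets the expiratory β parameters
  control the falling gradient, matching the intended feature semantics.
* **Sampling.** β parameters act per sample, so their physical meaning
  depends on dt; dt is an explicit configuration value everywhere and
  measured data are resampled (linear interpolation) to the configured dt
  before fitting so fitted β values are comparable.  Default dt = 0.005 s;
  the mouse-rate synthetic regimes use dt = 0.002 s (a realistic
  small-animal ventilator sampling rate, 758 samples per 0.66 breaths/s
  cycle).  Fewer than 50 samples/period is an error; fewer than 200
  triggers a warning.
* **Units.** ml, cmH2O, seconds; θ in breaths/s; phases in radians,
  applied additively inside the sinusoid.

## Estimation

Each breath is fitted by bounded multi-start nonlinear least squares
(scipy's trust-region reflective method; the choice of bound-constrained
local optimizer is not critical).  Initializations are drawn uniformly
from `center ± halfwidth` per free parameter (default halfwidth 30% of the
center), clipped to physically motivated box bounds; each start's draw
comes from a generator seeded with `(seed, stage, start_index)`, which
makes runs bit-reproducible and makes the best-of-n MSE nonincreasing in
the number of starts.  Optimizer tolerances default to 1e−10 (objective)
with 500 iterations per free parameter.  A simulation failure inside the
objective (degenerate normalization, invalid parameters) returns a large
penalty (1e12) instead of raising, so the multistart loop continues; such
starts are never counted as converged.

The result is the full distribution of local optima: best-MSE vector,
per-parameter median ± standard error of the mean over converged starts,
and a multimodality flag raised when the sorted solutions contain a gap
larger than 10% of the bound width.  A narrow unimodal distribution means
the parameter is well determined by that breath.

**Free/frozen sets.** Not every parameter is estimated in every setting:
by default the drive sharpnesses (a₁, a₂) and the two optional feature
groups (knee: a₃, b₃, φ₃, A_p3; plateau peaks: β₅, β₆, A_p2) are frozen at
configured values and only the duty offsets, phases, gradients, amplitudes
and baseline are free.  Feature groups are freed explicitly when the data
show the corresponding deformation.

**θ handling.** Three modes: `fixed` (θ frozen at the ventilator-set
respiratory rate), `from_volume` (θ estimated in the volume fit, then
frozen for the pressure fit — the library default), and `joint` (both
traces fitted simultaneously on scale-equalized stacked residuals).  On
single-period records at 1% noise, freely estimated θ retains ~1–3%
uncertainty that aliases into several-percent phase error (the shifted
optimum genuinely beats the truth's objective, i.e. honest maximum-
likelihood drift, not an optimizer artifact).  Since the respiratory rate
is a prescribed ventilator setting in every scenario the synthetic
generator emulates, the recovery studies use `theta_mode="fixed"`.

**Model comparison.** `compare_models` reports the ratio of the DILV
pressure-fit MSE to the single-compartment pressure MSE — pressure being
the signal both models predict — so the ratio is comparable across mouse
(ml) and human (hundreds of ml) scales.  Ratios below 1 favour the DILV
model; the volume-fit MSE, which has no single-compartment counterpart, is
reported alongside.  The single-compartment fit is ordinary least squares
of pressure on [volume, flow, intercept]; flow is derived by central
differences when not recorded, and Cs = 1/E.

## Synthetic data

The generator produces breaths with known ground truth under named
regimes: `healthy` and `injured` (pressure-controlled mouse breaths;
injured has slower inspiratory rise — larger β₁ — faster expiration,
smaller tidal volume and lower Cd), `vd`/`human` (a ventilated patient
with dyssynchrony-like plateau peaks, A_p2 > 0, β₅ ≈ 1.0014), `sc`
(breaths generated by the single-compartment model itself, for exact-
recovery checks) and `demo` (the canonical simulation example).  Two
conventions make the mouse regimes well-posed for recovery studies and are
deliberate design choices: the breath-alignment phases are set to 0.3 rad
in both regimes (alignment reflects where segmentation cuts the cycle, not
lung state, and near-zero true phases make relative error ill-defined),
and PEEP is the ventilation setting of 3 cmH2O for the same reason.  The
injury contrasts (β₁ up; β₂, A_v down; lower Cd) are preserved exactly.

Measurement noise is additive i.i.d. Gaussian, scaled to a fraction of
each trace's peak-to-peak amplitude (default 1%).  Breath-to-breath
variability is fractional Gaussian jitter on the physiological parameters
(β₁–β₄, A_v, A_p1, A_p3), clipped to validity.  Everything is reproducible
from `(seed, breath index)`.

What the generator does *not* emulate: correlated or heteroscedastic
sensor noise, ventilator controller dynamics and mode switches, patient
effort with breath-to-breath timing variation, drift, leaks, or secretions.
Passing recovery tests therefore demonstrate the estimator's correctness
and conditioning under the model's own assumptions, not performance on
measured recordings.

## Validation sizes

The test suite exercises: parameter recovery on 20 breaths per regime at
1% noise with 50 starts each (medians of all free parameters within 5%,
and within 1% at 0.1% noise; fitted Cd within 5%; injured < healthy), the
DILV vs single-compartment ratio on an 8-breath dyssynchrony-like cohort
(every per-breath ratio < 1), exact single-compartment recovery on its own
noise-free breaths (≤1e−8 relative), and closed-form oracles for every
primitive (arcsin duty fraction, tracker step response, leaky-diff
telescoping, periodicity after warm-up, unit normalization peaks).  These
sizes keep a desk-scale run in minutes on one core.

## Known limitations

* The model is descriptive, not mechanistic: parameters are anchored to
  waveform features, and their physiological reading (e.g. β₁ ↔ lower
  compliance/higher resistance) is interpretive, mode-dependent (PCV vs
  VCV), and valid only relative to a baseline.
* No structural identifiability analysis; the knee and plateau-peak groups
  are known to be only weakly identifiable, which is why they default to
  frozen.  The multistart distribution is the practical identifiability
  diagnostic.
* β values are tied to the configured dt (a per-sample recursion), so
  comparisons across datasets require a common dt.
* Segmentation assumes volume returns to a quiet end-expiratory baseline
  between breaths; it will mis-split severely auto-PEEPed or highly
  irregular records.
* The discrete recursions have no continuous-time (ODE) formulation here;
  converting to one is out of scope.
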