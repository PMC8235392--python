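# Methods

`thawspec` analyses multi-frequency electrical impedance of tissue along a
freeze–thaw trajectory. This note documents the models, the choices behind
them, and what the synthetic-data generator does and does not emulate.

## Impedance model and the Py statistic

A spectrum is the complex impedance Z(ω) = R + jX at 36 log-spaced
frequencies from 10 Hz to 510 kHz (capacitive reactance stored negative).
Around the beta dispersion — the radio-frequency relaxation caused by
charging of cell membranes — each spectrum is described by the
single-dispersion Cole model

    Z(ω) = R∞ + (R0 − R∞) / (1 + (jωτ)^α),

with zero- and infinite-frequency resistances R0 > R∞ > 0, characteristic
time τ > 0 and broadening exponent α ∈ (0, 1]. In the complex plane the
locus of (R, −X) is a circular arc depressed below the real axis by
(1 − α)·π/2. The membrane-integrity statistic is

    Py = (R0 − R∞) · 100 / R0    (percent).

Intact membranes force low-frequency current around cells (large R0) but
are short-circuited at high frequency (R∞), so Py measures the relative
size of the beta dispersion; membrane destruction drives it to zero. We
allow the degenerate equality R0 = R∞ in `ColeParameters` because Py = 0
(full membrane destruction) must be representable.

### Fitting

`fit_cole` minimizes Σ_k |Z_meas(f_k) − Z_model(f_k)|² / |Z_meas(f_k)|²
(relative complex least squares; spectra span orders of magnitude across
the grid, and 1/|Z|² weighting keeps high- and low-frequency points
comparably informative). The optimizer is a trust-region-reflective
Gauss–Newton (`scipy.optimize.least_squares`) over (R∞, R0 − R∞, ln τ, α)
with an analytic Jacobian, bounds R0 ≥ R∞ > 0, τ > 0, α ∈ (0, 1], and
tolerances 1e-14 within 500 evaluations. Non-convergence is reported via a
flag, never an exception.

Initialization is an algebraic (Kasa) circle fit through (R, −X): the two
real-axis intercepts of the least-squares circle estimate R0 and R∞
(larger intercept is R0), the depression angle of the centre gives α
(clipped to [0.3, 1]), and τ comes from the frequency of maximal −X
(ωτ = 1 at the apex) refined by parabolic interpolation in log-frequency,
which removes most of the grid-quantization error. Degenerate inputs
(collinear or constant points) fall back to R0 = max R, R∞ = min R,
τ = 1/(2π·median f), α = 0.8, flagged.

On noiseless model data the fit recovers all four parameters to better
than 1e-6 relative over R0 ∈ [50, 5000] Ω, R∞/R0 ∈ [0.2, 0.9],
τ ∈ [1e-7, 1e-3] s, α ∈ [0.5, 1] (tested); at 1 % complex noise the
median relative error of R0 and R∞ stays below 5 % and the median |Py|
error below 1 Py unit.

## Scalar descriptors

* magnitude |Z| = √(R² + X²) and phase φ = arctan(X/R), reported in
  degrees (the plotting convention in bioimpedance).
* relative storage change: the `corrected` default returns
  100·(Z₀ − Z_i)/Z₀, so a loss of impedance is a positive percentage
  bounded by 100 at total loss; the plus-sign variant seen in print,
  100·(Z₀ + Z_i)/Z₀, cannot express a decrease as less than 100 % and is
  kept only behind `mode="as_printed"`.
* fresh-vs-thawed indices R_index = (R_un − R_ft)/R_un and
  X_index = (X_un − X_ft)/X_un. These are scale-invariant by construction,
  so differences in sample geometry (which rescale all ohm values) cancel.
  X_index is undefined (NaN) where X_un = 0.
* impedance change rate: ICR_k = (|Z|_{k−1} − |Z|_k)/(|Z|_{k−1}·Δaxis_k),
  a normalized backward difference per second or per degC. No standard
  formula exists for this quantity; the normalized form is dimensionally
  sensible on both axes and makes the phase-change spike comparable across
  samples of different size. The evaluation frequency is a parameter
  (lowest grid frequency by default) since no canonical choice exists.

## Group statistics

Py values are compared between thawing groups per temperature (0, 0.5, …,
4 degC, plus a "next day" row) with a two-sided Mann–Whitney U test,
U = min(U_a, U_b) with midrank ties. The exact method enumerates all
C(n_a+n_b, n_a) group assignments; its two-sided p is the null probability
of |U_a − n_a·n_b/2| at least as large as observed, which is well defined
under ties and reduces to the usual two-sided value on tie-free data.
Enumeration is used automatically up to combined n = 12 (924 assignments);
above that a tie-corrected normal approximation with 0.5 continuity
correction is used — at 10 vs 10 the two agree to better than 0.01
(tested). Summaries use sample SD (ddof = 1) and IQR = Q3 − Q1 with
linear-interpolation quantiles; these conventions are stated because
quantile conventions differ across software. No multiple-testing
correction is applied across temperature rows (matching the analysis the
package reproduces); a clearly-labelled Holm-adjusted column is emitted
alongside as an extension.

Drip (thaw) loss is 100·(initial − final)/initial, optionally rescaled
linearly to a common storage duration (samples are weighed after 16–26 h),
and compared with a two-sided Welch t-test.

## Synthetic freeze–thaw generator

No raw measurements are distributed with the study this package
reimplements, so a simulator supplies inputs with the statistical
structure the analysis assumes. Per physical sample:

1. **Thermal trajectory.** A lumped (zero-dimensional) model
   dT/dt = k·(T_env − T)/c_app(T) is stepped explicitly (Euler; a
   stability guard rejects k·dt ≥ 1). c_app is 1 outside the melting band
   [−12, −1.5] degC and rises to `latent_boost` (default 8, Gaussian bump)
   inside it, standing in for latent heat. This reproduces the plateau of
   real thawing curves with three parameters; a spatial heat-transfer PDE
   would need thermal properties that are not available. Defaults
   k = 5e-4 s⁻¹ (water bath) and 5e-5 s⁻¹ (air) give ≈3 h and ≈30 h
   thawing of a 180 g piece from −75 degC — realistic magnitudes; only
   their ratio matters to the analysis. In the latent-heat-free limit the
   stepping matches Newton heating to <0.1 degC at dt = 1 s.
   Ice fraction ramps smoothly (renormalized normal CDF) from 1 to 0
   across the band.
2. **Membrane damage.** One scalar d ∈ [0, 1] per sample accrues at a
   constant rate while the core is inside the melting band (slow thawing
   spends ~10x longer there) and, much more slowly, during post-thaw
   chilled storage. Group end-of-thaw damage distributions are truncated
   Gaussians on [0, 1] calibrated so the induced ground-truth Py at 4 degC
   has the configured mean/SD per group — defaults (16.1, 3.90) fast and
   (10.2, 3.35) slow, with next-day targets (4.65, 1.85) and (3.41, 3.27).
   Calibration matches the first two moments of Py under the truncated
   density by deterministic quadrature; Monte-Carlo verification holds to
   5 % relative (the slow next-day target sits at the edge of what the
   truncated-Gaussian family can express and is matched to ≈3 %).
   Each sample's transition rate is set so its drawn endpoint is reached
   exactly when it leaves the band.
3. **State → Cole parameters.** R∞ scales with ionic mobility as
   1/(1 + 0.02·(T − 4)) — the 2 %/degC magnitude of electrolyte
   conductivity; only relative behaviour matters — and with a frozen
   factor (1 + ε)/(1 − ice + ε), ε = 0.02, i.e. exactly 1 when melted and
   51x at full ice. The linear mobility law is floored at the bottom of
   the melt band: it describes the liquid/mushy regime, and letting it run
   to its −46 degC singularity both diverges and (tested) moves the
   steepest |Z| drop out of the melt band. The dispersion magnitude
   R0 − R∞ shrinks as (1 − d): damage 1 gives Py = 0. Base parameters for
   intact tissue at 4 degC are R0 = 66.7 Ω, R∞ = 50 Ω (Py = 25, safely
   above the highest group target), τ = 10 µs (apex at ≈16 kHz,
   mid-grid), α = 0.85.
4. **Between-sample variation and group structure.** A common lognormal
   scale factor (sd 5 %) on R0 and R∞ models geometry (Py is invariant
   under it); τ is shifted ±10 % per group (fast low, slow high; the
   `tau_group_shift` knob, default 0.2 total) and jittered lognormally
   (sd 8 %) per sample; α is jittered (sd 0.015). The τ shift gives the
   full-spectrum classifier group structure beyond the Py overlap — Py
   alone does not determine how separable whole spectra are.
5. **Noise.** Z_k → Z_k·(1 + s·(g1 + j·g2)) with independent standard
   Gaussians per frequency, s = 0.01 by default; points whose noisy
   resistance is non-positive are redrawn. Note this puts noise of
   magnitude s·|Z| on *both* components, so the small reactance channel
   carries proportionally much more noise than the resistance channel.
6. **Drip loss** is sampled directly from configured distributions with
   equal group means (8 ± 1.5 % of initial weight) — the null result the
   comparison is expected to reproduce; the generator makes no attempt to
   model exudate physics.

Everything is reproducible bit-for-bit from the single config seed.

What the generator does **not** emulate: spatial temperature gradients
(core vs surface), electrode polarization, recrystallization
microphysics, anisotropy, the slight Py decline with temperature seen in
real data between 0 and 4 degC (our Py is flat to slightly rising across
that range because damage has stopped accruing), and any damage–drip
coupling. Passing tests therefore validate the pipeline's statistical
machinery under the assumed structure, not the biology of real pork loin.

## LSTM classifier

Each example is one 36-point spectrum (resistance or reactance channel);
the recurrence runs along the ascending frequency axis. Architecture:
LSTM(32) → per-time-step, feature-wise batch normalization (batch
statistics in training, momentum-0.9 running averages in evaluation) →
inverted dropout → LSTM(32) → dense softmax over the final hidden state.
Training: mini-batch Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8) on
cross-entropy + L2 (1e-4) over the weight matrices, batch 16, learning
rate 3e-3, dropout 0.4, up to 300 epochs with early stopping (patience
60) on held-out loss, restoring the best epoch. The original study tuned
batch size, ridge penalty, learning rate, units and dropout without
reporting values; these defaults come from a sweep on the default
synthetic cohort. All gradients are exact backpropagation through time
(including through the batch-statistics dependence of batch norm) and are
verified against central finite differences to 1e-5 relative.

The 80/20 split is stratified over individual spectra by default — the
literal protocol of the reproduced experiment (180 rows, 90 per class,
144/36 split). Because the 9 spectra of one physical sample are
correlated, this split leaks sample identity into the test set; a
group-aware mode (`groups=` argument) keeps all spectra of a physical
sample on one side and gives a stricter generalization estimate. Whether
the original experiment grouped by sample is not stated there; we default
to the ungrouped reading because the reported design arithmetic (a flat
80/20 over 180 samples) matches it.

On the default cohort the reactance-channel test accuracy is limited to
≈0.85–0.95 across seeds and the resistance channel reaches ≈0.9–1.0: the
multiplicative noise model (point 5 above) attenuates the reactance
advantage. With noise disabled the ordering flips decisively (reactance
≈0.95, resistance ≈0.7 for a reference SVM), which is the membrane
signal the reactance channel is expected to carry.

## Pipeline

`run_pipeline` chains simulate → fit → metrics → compare → classify →
report; each stage writes its artifacts (CSV/JSON) before the next runs,
and a manifest records a SHA-256 checksum per artifact. Stage seeds are
derived from the single run seed via `numpy.random.SeedSequence`, so a
rerun with the same config reproduces identical checksums (tested). The
`thawspec` CLI is a thin wrapper exposing each stage as a subcommand;
logs go to stderr, results only to files.

## Numerical conventions and degenerate inputs

* Temperature matching tolerance 0.25 degC (half the 0.5 degC
  measurement step); "next day" measurements are encoded as thaw-treated
  rows without a thaw clock (empty `time_s`), core temperature 2–4 degC.
* ICR pairs with zero axis increment are skipped and flagged; a
  descending axis is an error.
* Two constant equal groups give t = 0, p = 1 by convention.
* An all-real, constant spectrum (no dispersion) falls back to flagged
  initialization and fits to Py ≈ 0.
* Problem sizes in the test suite (replicate counts, cohort sizes, epoch
  caps in pipeline tests) are chosen so the whole suite runs in a few
  minutes on one CPU while keeping every statistical check well-powered.

## Known limitations

* The simulator's damage scalar is a caricature: real freeze–thaw injury
  is spatially heterogeneous and partially reversible (fluid
  reabsorption), which the monotone d cannot express.
* The truncated-Gaussian damage family cannot express strongly skewed Py
  targets exactly (slow next-day case above).
* The Cole fit assumes a single dispersion; electrode polarization or a
  second dispersion would bias R0.
* The exact MWU enumerates assignments and is practical only to combined
  n ≈ 16; the auto threshold (12) stays well inside that.
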