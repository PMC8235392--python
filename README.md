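# thawspec

Bioimpedance analysis of freeze–thaw damage in tissue, built for the
question a food-quality lab asks: *can electrical impedance spectroscopy
tell how a frozen sample was thawed?* Freezing and thawing destroy cell
membranes; since intact membranes act as capacitors that block
low-frequency current, the damage is visible in the complex impedance
spectrum. `thawspec` packages the full analysis chain:

* **Cole-model fitting** of 36-point complex spectra (10 Hz – 510 kHz),
  Z(ω) = R∞ + (R0 − R∞)/(1 + (jωτ)^α), by relative complex least squares
  with an algebraic circle-fit initialization;
* the **Py membrane-integrity statistic**, Py = (R0 − R∞)·100/R0 — the
  relative size of the beta dispersion, which shrinks to zero as membranes
  are destroyed;
* **fresh-vs-thawed indices** (R_un − R_ft)/R_un and (X_un − X_ft)/X_un,
  geometry-free ratios, plus magnitude/phase and the impedance change
  rate (ICR) along a thawing trajectory;
* **per-temperature group comparison** of Py (fast water-bath vs slow air
  thawing) with exact or tie-corrected-normal Mann–Whitney U tests, and a
  Welch t-test on time-normalized drip loss;
* a **seeded freeze–thaw simulator** — lumped thermal model with a
  latent-heat plateau, scalar membrane-damage dynamics calibrated to
  target Py distributions, and noisy Cole spectra — standing in for
  laboratory measurements that were never deposited;
* a from-scratch, gradient-checked **two-layer LSTM** (batch norm,
  dropout, softmax head, Adam, BPTT in numpy) that classifies thawing
  method from a single spectrum's resistance or reactance channel.

Everything is importable from `thawspec`; a thin `thawspec` CLI chains
simulate → fit → metrics → compare → classify → report with per-artifact
checksums.

## Worked example

Generate the default synthetic cohort (10 fast- plus 10 slow-thawed
samples, measured at each 0.5 degC from 0 to 4 degC and once more the
next day), fit every spectrum and compare group Py per temperature:

```sh
python examples/03_group_comparison.py
```

```
 T (degC)  fast mean  slow mean    MWU p
        0      16.13      10.31   0.0046
      0.5      16.33      10.24   0.0058
        1      16.60      10.39   0.0046
      1.5      16.31      10.48   0.0046
        2      16.75      10.42   0.0046
      2.5      16.77      10.59   0.0036
        3      16.54      10.79   0.0058
      3.5      16.87      10.64   0.0046
        4      17.12      10.90   0.0046
 next_day       5.82       3.46   0.0257
```

Each row summarizes ten fitted Py values per group at one core
temperature. Water-bath (fast) thawed samples keep a higher Py — more
intact membranes — throughout thawing (p < 0.01); after >16 h of chilled
storage both groups collapse toward low Py and the gap shrinks sharply.

Train the spectrum classifiers on the same cohort:

```sh
python examples/04_classify_thawing.py
```

```
reactance  channel: test accuracy 0.8056, test loss 0.4364 (83 epochs, best at 22)
resistance channel: test accuracy 0.9167, test loss 0.2734 (94 epochs, best at 33)
```

Accuracy is the fraction of 36 held-out spectra assigned to the correct
thawing method (stratified 80/20 split over the 180 spectra). The other
examples show the thermal curves with their latent-heat plateau (`01`),
a single Cole fit (`02`), and the scalar metrics and ICR spike at phase
change (`05`).

The full pipeline, as a shell command:

```sh
thawspec run -o out --seed 5
```

writes `spectra.csv`, `cole_fits.csv`, `metrics.csv`, `py_comparison.csv`,
trained model JSONs, per-sample predictions, a JSON report and a
`manifest.json` with SHA-256 checksums (bit-identical on rerun with the
same seed).

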