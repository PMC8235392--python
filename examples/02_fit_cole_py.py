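"""Fit the Cole model to one noisy spectrum and read off the Py statistic.

Py = (R0 - Rinf) * 100 / R0 measures the beta dispersion: the share of
low-frequency resistance contributed by intact, capacitive cell membranes.
Freeze-thaw damage shrinks it toward zero.
"""

import numpy as np

import thawspec as ts

grid = ts.FrequencyGrid.default()          # 36 log-spaced points, 10 Hz - 510 kHz
truth = ts.ColeParameters(r0_ohm=66.7, rinf_ohm=50.0, tau_s=1e-5, alpha=0.85)
rng = np.random.default_rng(0)

sample = ts.synthesize_spectrum(truth, grid, noise_sd=0.01, rng=rng)
fit = ts.fit_cole(sample)

print(f"true parameters:   R0={truth.r0_ohm:7.2f}  Rinf={truth.rinf_ohm:6.2f}  "
      f"tau={truth.tau_s:.2e}  alpha={truth.alpha:.3f}  Py={ts.py_parameter(truth):5.2f}")
print(f"fitted parameters: R0={fit.params.r0_ohm:7.2f}  Rinf={fit.params.rinf_ohm:6.2f}  "
      f"tau={fit.params.tau_s:.2e}  alpha={fit.params.alpha:.3f}  "
      f"Py={ts.py_parameter(fit.params):5.2f}")
print(f"converged={fit.converged} after {fit.n_iter} evaluations, "
      f"residual RMS {fit.residual_rms_ohm:.3f} ohm")
print("\nWith 1% complex measurement noise the fitted Py lands well within one")
print("Py unit of the ground truth - the precision the group comparison relies on.")
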