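"""Train the two-layer LSTM to tell fast- from slow-thawed samples.

Each example is one 36-point spectrum (resistance or reactance channel);
the 180 spectra (20 samples x 9 temperatures) are split 80/20 stratified
by class, as in the discrimination experiment the package reproduces.
"""

import thawspec as ts
from thawspec.lstm import spectrum_dataset

cohort = ts.generate_cohort(ts.SimulatorConfig(seed=0))

for channel in ("X", "R"):
    X, labels, _ = spectrum_dataset(cohort, channel=channel)
    cfg = ts.LSTMConfig(seed=1, input_channel=channel)
    model, report = ts.train_classifier(X, labels, cfg)
    name = "reactance " if channel == "X" else "resistance"
    print(f"{name} channel: test accuracy {report.test_accuracy:.4f}, "
          f"test loss {report.test_loss:.4f} "
          f"({len(report.history)} epochs, best at {report.best_epoch})")

print("\nAccuracy is the fraction of held-out spectra assigned to the correct")
print("thawing method; loss is the mean cross-entropy of the softmax output.")
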