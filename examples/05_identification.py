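"""Biometric identification before and after compressed-sensing reconstruction.

A jittered population of synthetic subjects is generated; the one-vs-one SVM
bank is trained on original feature windows, and held-out windows are scored
both as generated and after the sense -> SWAMP round trip.  If reconstruction
preserves morphology, the two recognition rates coincide.
"""

import cardiocs as cc

out = cc.recognition_experiment(n_subjects=8, windows_per_subject=6, seed=0)
print(f"training windows: {out.n_train}, test windows: {out.n_test}")
print(f"mean reconstruction MR on test windows: {out.mean_mr:.4f}")
print(f"recognition rate before reconstruction: {out.accuracy_before:.4f}")
print(f"recognition rate after  reconstruction: {out.accuracy_after:.4f}")
print(f"difference: {out.difference:+.4f}")
# A near-zero difference shows identification survives 0.7-ratio compression:
# the features carrying identity are intact in the reconstructed signals.
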