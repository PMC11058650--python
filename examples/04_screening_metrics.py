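"""Score a virtual screen with GH, F1, enrichment factor and ROC AUC.

Starts from a worked confusion matrix (83 true positives, 17 false negatives,
31 false positives, 237 true negatives), then shows ranking metrics on a
synthetic screen with the 1:50 active:decoy imbalance.
"""

import numpy as np

from pharmscreen.metrics import ConfusionCounts, RankedScreen, ef, f1, gh, rates, roc_auc

counts = ConfusionCounts(tp=83, fn=17, fp=31, tn=237)
r = rates(counts)
print(f"recall: {100 * r['recall']:.2f}%  "
      f"false positive rate: {100 * r['fpr']:.2f}%")
print("-> 31 false alarms among 268 true inactives is an 11.57% FPR")
print(f"GH score: {gh(counts):.3f}   F1: {f1(counts):.3f}")
print("-> GH = (0.75 P + 0.25 R) x specificity rewards precise, specific screens")

rng = np.random.default_rng(0)
labels = np.r_[np.ones(100, dtype=int), np.zeros(5000, dtype=int)]
scores = labels + rng.normal(0, 0.7, labels.size)
screen = RankedScreen(scores=scores, labels=labels)
_, _, auc = roc_auc(screen)
print(f"synthetic screen (100 actives / 5000 decoys): AUC = {auc:.3f}")
print(f"EF1% = {ef(screen, 1.0):.2f}, EF5% = {ef(screen, 5.0):.2f}")
print("-> EF1% is the active concentration in the top 1% relative to random"
      f" picking; the ceiling at this imbalance is {ef(RankedScreen(scores=-np.arange(5100.0), labels=labels), 1.0):.0f}")
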