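"""Recompute the shipped validation-study fixtures.

Sums the worked example's per-criterion separation distances into channel
totals, forms closeness coefficients, and re-derives the two held-out
test-set accuracies from the shipped confusion matrices.
"""

import numpy as np

from pcoscreen.datasets import iter_reference_profiles, reference_confusion_matrices
from pcoscreen.metrics import ConfusionMatrix, accuracy
from pcoscreen.topsis import SeparationProfile, closeness_coefficients, rank_alternatives

for channel in ("physical", "mental"):
    rows = sorted(
        (alt, ds, dn) for ch, alt, ds, dn in iter_reference_profiles() if ch == channel
    )
    profile = closeness_coefficients(SeparationProfile(
        tuple(a for a, _, _ in rows),
        tuple(d for _, d, _ in rows),
        tuple(d for _, _, d in rows),
    ))
    ranked = rank_alternatives(profile)
    ccs = dict(zip(profile.alternatives, profile.cc))
    print(f"{channel}: " + " > ".join(f"{a} (CC={ccs[a]:.3f})" for a in ranked))

ref = reference_confusion_matrices()
for name in ("fuzzy_topsis", "svm"):
    cm = ConfusionMatrix(tuple(ref["classes"]), np.array(ref[name]))
    print(f"{name}: held-out accuracy {accuracy(cm):.2f}%")
# The top-ranked level per channel (P1, M1) is the worked example's
# screening outcome; the accuracies are the study-level regression anchors.
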