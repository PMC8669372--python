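"""Derive criterion weights from fuzzy AHP pairwise judgments.

Three toy criteria are compared pairwise on the Saaty-style linguistic
scale; the chain geometric-means -> fuzzy weights -> center-of-area
defuzzification -> normalisation yields crisp weights summing to one.
"""

from pcoscreen import build_comparison_matrix, derive_weights

judgments = [
    ("cycle_regularity", "weight_gain", "Moderate important"),
    ("cycle_regularity", "junk_food", "Strong important"),
    ("weight_gain", "junk_food", "Intermediate (2)"),
]
matrix = build_comparison_matrix(
    judgments, ["cycle_regularity", "weight_gain", "junk_food"]
)
weights = derive_weights(matrix)
for cid, w in zip(weights.criteria, weights.normalized):
    print(f"{cid:>18}: {w:.4f}")
print(f"{'sum':>18}: {sum(weights.normalized):.4f}")
# Larger normalised weight = more influence on the TOPSIS ranking; the
# criterion judged moderately-to-strongly more important dominates.
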