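"""Worked examples on published summary statistics.

Attenuation-corrected correlations, differences between the best
correlations of two data sources, and a Fisher confidence interval —
pure arithmetic on printed inputs, using the evaluation module.
"""

from lexnorm import disattenuate, fisher_ci, round_half_up

# best leave-one-out correlation of association-based k-NN predictions with
# human ratings, and the split-half reliability of those ratings
cases = [
    ("valence (Dutch)", 0.91, 0.99),
    ("arousal (Dutch)", 0.84, 0.97),
    ("dominance (Dutch)", 0.84, 0.96),
    ("valence (English)", 0.86, 0.91),
    ("arousal (English)", 0.69, 0.69),
    ("dominance (English)", 0.75, 0.77),
]
print("correction for attenuation: r / sqrt(reliability)")
for label, r, rel in cases:
    corrected = disattenuate(r, rel, 1.0)
    print(f"  {label:20s} r = {r:.2f}, reliability = {rel:.2f} "
          f"-> corrected r = {round_half_up(corrected):.2f}")
print("(the corrected values estimate the correlation with noise-free ratings;")
print(" prediction reliability is conventionally set to 1)")

print()
print("association minus co-occurrence best correlations (same 2,831 words):")
for label, ra, rt in [
    ("valence", 0.91, 0.78),
    ("arousal", 0.84, 0.73),
    ("dominance", 0.84, 0.66),
    ("age of acquisition", 0.71, 0.64),
]:
    print(f"  {label:20s} {ra:.2f} - {rt:.2f} = {round_half_up(ra - rt):.2f}")

print()
rep = fisher_ci(0.87, 2831)
print(f"Fisher 95% CI for r = .87 at n = 2,831 (concreteness): "
      f"({round_half_up(rep.ci_low):.2f}-{round_half_up(rep.ci_high):.2f})")
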