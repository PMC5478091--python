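# Example simulation design for `miaconcord simulate --design ...`.
# Mirrors the 54-case pediatric validation series: CDA category frequencies,
# the observed MIA-given-CDA misclassification rows, and the coincidence-depth
# distribution among category-concordant pairs.
n_cases: 54
seed: 7
# fixed category order: infectious, malignant, congenital, other, nonconclusive
category_probs: [0.7777777778, 0.1296296296, 0.0370370370, 0.0555555556, 0.0]
confusion:
  - [0.9285714286, 0.0, 0.0, 0.0238095238, 0.0476190476]  # CDA infectious
  - [0.0, 1.0, 0.0, 0.0, 0.0]                             # CDA malignant
  - [1.0, 0.0, 0.0, 0.0, 0.0]                             # CDA congenital
  - [0.3333333333, 0.0, 0.0, 0.6666666667, 0.0]           # CDA other
  - [0.0, 0.0, 0.0, 0.0, 1.0]                             # CDA nonconclusive
# P(perfect, almost_perfect, moderate, low); remainder -> "none"
depth_agreement: [0.5, 0.1666666667, 0.0833333333, 0.0625]
evidence_certainty:
  cda: {low: 0.0555555556, moderate: 0.1296296296, high: 0.4074074074, very_high: 0.4074074074}
  mia: {low: 0.0769230769, moderate: 0.2115384615, high: 0.3653846154, very_high: 0.3461538462}
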