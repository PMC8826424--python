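# Verbal strength-of-evidence scales: ordered bands (lower exclusive,
# upper inclusive] of the likelihood ratio for the supported proposition.
# "ENFSI" follows the European Network of Forensic Science Institutes
# guideline wording; "literature" the scale used by Marquis et al.
# upper: null means unbounded above.
scales:
  ENFSI:
    - {lower: 1, upper: 1, label: "Null"}
    - {lower: 1, upper: 10, label: "Slight or limited support"}
    - {lower: 10, upper: 100, label: "Moderate support"}
    - {lower: 100, upper: 1000, label: "Moderately strong support"}
    - {lower: 1000, upper: 10000, label: "Strong support"}
    - {lower: 10000, upper: null, label: "Very strong support"}
  literature:
    - {lower: 1, upper: 1, label: "Null"}
    - {lower: 1, upper: 10, label: "Weak or limited support"}
    - {lower: 10, upper: 100, label: "Moderate support"}
    - {lower: 100, upper: 1000, label: "Strong support"}
    - {lower: 1000, upper: 10000, label: "Very strong support"}
    - {lower: 10000, upper: null, label: "Extremely strong support"}
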