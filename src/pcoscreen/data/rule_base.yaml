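# Clinician-validated fusion rules: (PCOS level, mental-health level) -> category.
# A1 = PCOS and mental-health issues, A2 = PCOS only, A3 = mental-health only,
# A4 = normal.  Levels: 1 = high, 2 = normal, 3 = moderate.
rules:
  - [P1, M1, A1]
  - [P1, M2, A2]
  - [P1, M3, A1]
  - [P2, M1, A3]
  - [P2, M2, A4]
  - [P2, M3, A3]
  - [P3, M1, A1]
  - [P3, M2, A2]
  - [P3, M3, A1]
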