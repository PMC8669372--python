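# Test-set confusion matrices from the instrument's clinical validation
# study (167 held-out subjects; rows = actual class, columns = predicted,
# class order A1..A4).  Shipped as regression fixtures for the metrics
# module.
classes: [A1, A2, A3, A4]
svm:
  - [37, 0, 0, 0]
  - [0, 24, 0, 0]
  - [1, 0, 38, 4]
  - [0, 3, 2, 58]
fuzzy_topsis:
  - [37, 0, 0, 0]
  - [0, 24, 0, 0]
  - [0, 0, 41, 2]
  - [0, 0, 1, 62]
# Channel-level composition of the same 167 test subjects: counts screened
# into each condition-positive level, used by the wellness indicators.
test_counts:
  total: 167
  P1: 52
  P3: 4
  M1: 83
  M3: 1
  A1: 37
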