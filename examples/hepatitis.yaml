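# Dataset config for the UCI Hepatitis table (class column first,
# "?" missing marker, no header).  Attribute kinds follow the UCI
# documentation; override per local file layout as needed.
path: hepatitis.data
format: csv
class_column: 0
header: false
missing_marker: "?"
kinds:
  1: continuous    # age
  2: categorical   # sex
  3: categorical   # steroid
  4: categorical   # antivirals
  5: categorical   # fatigue
  6: categorical   # malaise
  7: categorical   # anorexia
  8: categorical   # liver big
  9: categorical   # liver firm
  10: categorical  # spleen palpable
  11: categorical  # spiders
  12: categorical  # ascites
  13: categorical  # varices
  14: continuous   # bilirubin
  15: continuous   # alk phosphate
  16: continuous   # sgot
  17: continuous   # albumin
  18: continuous   # protime
  19: categorical  # histology
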