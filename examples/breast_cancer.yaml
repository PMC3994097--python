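# Dataset config for the UCI Wisconsin Breast Cancer table: sample id in
# the first column is not a feature, so drop it before use or point
# class_column at the last column of the 10-column layout.  Class last,
# "?" missing marker (16 rows carry one), no header; all features are
# integer-valued clinical scores treated as continuous.
path: breast-cancer-wisconsin.data
format: csv
class_column: -1
header: false
missing_marker: "?"
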