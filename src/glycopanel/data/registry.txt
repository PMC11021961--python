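# Default MALDI-TOF annotation target list: 27 serum N-glycan compositions.
# One canonical composition string per line; '#' starts a comment.
# High-mannose series
H5N2
H6N2
H7N2
H8N2
H9N2
# Hybrid
H5N3
H6N3
H5N3S1
# Complex, neutral
H3N4
H3N4F1
H4N4
H4N4F1
H5N4
H5N4F1
H5N5
H5N5F1
H6N5
H6N5F1
H7N6
# Complex, sialylated
H5N4S1
H5N4F1S1
H5N4S2
H5N4F1S2
H6N5S1
H6N5F1S1
H6N5S2
H6N5S3
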