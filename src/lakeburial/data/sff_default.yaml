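# Sediment focusing factor (SFF) defaults.
#
# EXTERNAL ASSUMPTIONS, NOT MEASURED VALUES.  The SFF corrects a single core
# taken in the preferential deposition area down to a whole-lake average.
# Depth-class values and the slope relation follow the conventions of the
# focusing-factor literature (Blais & Kalff 1995; Mendonca et al. 2017) but
# the exact numbers are placeholders: override this file with values fitted
# to your own lake set before interpreting whole-lake rates quantitatively.
#
# depth_classes: maximum lake depth bins in metres (upper edges; last is open)
depth_classes:
  - {max_depth_le: 5,   sff: 1.0}
  - {max_depth_le: 10,  sff: 1.4}
  - {max_depth_le: 30,  sff: 1.9}
  - {max_depth_le: 90,  sff: 2.4}
  - {max_depth_le: .inf, sff: 3.0}
# SFF(slope) = max(1, intercept + coef * mean lake slope in %)
slope_relation:
  intercept: 1.0
  coef: 0.06
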