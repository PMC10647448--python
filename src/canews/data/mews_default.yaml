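# Default MEWS scoring table.
#
# EXTERNAL PROVENANCE: band cut-offs transcribed from the published Modified
# Early Warning Score of Subbe CP, Kruger M, Rutherford P, Gemmel L.
# "Validation of a modified Early Warning Score in medical admissions."
# QJM 2001;94:521-526.  Edit or replace to use a local variant.
#
# Numeric bands are closed below / open above: a value v matches the band
# with lo <= v < hi.  Omitted lo/hi mean -inf/+inf.  Consciousness bands are
# keyed by AVPU level.
sbp:          # systolic blood pressure, mmHg
  - {hi: 71, points: 3}
  - {lo: 71, hi: 81, points: 2}
  - {lo: 81, hi: 101, points: 1}
  - {lo: 101, hi: 200, points: 0}
  - {lo: 200, points: 2}
hr:           # heart rate, beats/min
  - {hi: 41, points: 2}
  - {lo: 41, hi: 51, points: 1}
  - {lo: 51, hi: 101, points: 0}
  - {lo: 101, hi: 111, points: 1}
  - {lo: 111, hi: 130, points: 2}
  - {lo: 130, points: 3}
rr:           # respiratory rate, breaths/min
  - {hi: 9, points: 2}
  - {lo: 9, hi: 15, points: 0}
  - {lo: 15, hi: 21, points: 1}
  - {lo: 21, hi: 30, points: 2}
  - {lo: 30, points: 3}
bt:           # body temperature, degrees Celsius
  - {hi: 35, points: 2}
  - {lo: 35, hi: 38.5, points: 0}
  - {lo: 38.5, points: 2}
consciousness:
  A: 0
  V: 1
  P: 2
  U: 3
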