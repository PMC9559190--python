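# Male-rat -> male-mouse parameter differences (relative changes), plus
# species-level overrides: nephron count, class weights (superficial share
# 0.82 with the juxtamedullary pool normalised to sum to one) and the
# juxtamedullary SNGFR premium (20% in mice).
column: rat_male_to_mouse_male
overrides:
  nephron_count: 12000
  jm_sngfr_ratio: 1.20
  class_weights:
    SF: 0.82
    JM1: 0.072
    JM2: 0.054
    JM3: 0.027
    JM4: 0.018
    JM5: 0.009
deltas:
  - {parameter: sngfr, change: -0.667}
  # proximal tubule: length -63.6%, diameter -20%
  - {segments: [PCT, S3], parameter: length, change: -0.636}
  - {segments: [PCT, S3], parameter: diameter, change: -0.20}
  - {segments: [PCT, S3], parameter: NHE3, change: -0.32}
  # short descending limb: length -42.9%, diameter -40%
  - {segments: [SDL], parameter: length, change: -0.429}
  - {segments: [SDL], parameter: diameter, change: -0.40}
  # thick ascending limb: length -35%, diameter -10%
  - {segments: [mTAL, cTAL], parameter: length, change: -0.35}
  - {segments: [mTAL, cTAL], parameter: diameter, change: -0.10}
  - {segments: [mTAL, cTAL], parameter: NKA, change: -0.13}
  # distal convoluted tubule: length -30%, diameter -6.7%
  - {segments: [DCTe, DCTl], parameter: length, change: -0.30}
  - {segments: [DCTe, DCTl], parameter: diameter, change: -0.067}
  - {segments: [DCTe, DCTl], parameter: NCC, change: -0.27}
  - {segments: [DCTe, DCTl], parameter: NKA, change: -0.20}
  - {segments: [DCTe, DCTl], parameter: apical_PK, change: -0.67}
  - {segments: [DCTl], parameter: ENaC, change: -0.49, note: "late DCT carries ENaC"}
  # connecting tubule: length -60%, diameter -16.7%
  - {segments: [CNT], parameter: length, change: -0.60}
  - {segments: [CNT], parameter: diameter, change: -0.167}
  - {segments: [CNT], parameter: apical_PK, change: -0.75}
  - {segments: [CNT], parameter: HKA, change: -0.50}
  # cortical collecting duct: length -50%, diameter -4%
  - {segments: [CCD], parameter: length, change: -0.50}
  - {segments: [CCD], parameter: diameter, change: -0.04}
  - {segments: [CCD], parameter: HKA, change: -0.50}
  # outer-medullary collecting duct: length -35%, diameter -4%
  - {segments: [OMCD], parameter: length, change: -0.35}
  - {segments: [OMCD], parameter: diameter, change: -0.04}
  - {segments: [OMCD], parameter: HKA, change: -0.50}
  # inner-medullary collecting duct: length -32%, diameter -7%
  - {segments: [IMCD], parameter: length, change: -0.32}
  - {segments: [IMCD], parameter: diameter, change: -0.07}
  - {segments: [IMCD], parameter: NHE, change: -0.67}
  - {segments: [IMCD], parameter: NKA, change: -0.25}
  - {segments: [IMCD], parameter: HKA, change: -0.75}
  - {segments: [IMCD], parameter: para_PNa, change: -0.33}
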