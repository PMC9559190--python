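# Male-mouse -> female-mouse parameter differences (relative changes).
# IMCD rows printed with stray trailing marks in the source table are read
# as the percentage only.
column: mouse_male_to_female
deltas:
  - {parameter: sngfr, change: -0.20}
  - {parameter: plasma_K, change: -0.07}
  # proximal tubule
  - {segments: [PCT, S3], parameter: length, change: -0.15}
  - {segments: [PCT, S3], parameter: diameter, change: -0.15}
  - {segments: [PCT, S3], parameter: NHE3, change: -0.35}
  - {segments: [PCT], parameter: SGLT2, change: null, note: "no change"}
  - {segments: [PCT, S3], parameter: NaPi, change: -0.50}
  - {segments: [PCT, S3], parameter: para_PNa, change: -0.40}
  - {segments: [PCT, S3], parameter: para_PCl, change: -0.40}
  - {segments: [PCT, S3], parameter: apical_Pf, change: 0.40}
  # short descending limb: no change
  - {segments: [SDL], parameter: length, change: null, note: "no change"}
  # thick ascending limb
  - {segments: [mTAL, cTAL], parameter: length, change: null, note: "no change"}
  - {segments: [mTAL, cTAL], parameter: NKA, change: -0.10}
  - {segments: [mTAL, cTAL], parameter: NHE, change: -0.25}
  - {segments: [mTAL, cTAL], parameter: NaPi, change: null, note: "no change"}
  - {segments: [mTAL, cTAL], parameter: NKCC2, change: 0.20}
  - {segments: [mTAL, cTAL], parameter: KCC4, change: 0.64}
  - {segments: [mTAL, cTAL], parameter: para_PNa, change: null, note: "no change"}
  - {segments: [mTAL, cTAL], parameter: para_PCl, change: null, note: "no change"}
  # distal convoluted tubule
  - {segments: [DCTe, DCTl], parameter: length, change: null, note: "no change"}
  - {segments: [DCTe, DCTl], parameter: NCC, change: 1.00}
  - {segments: [DCTe, DCTl], parameter: NKA, change: 0.25}
  - {segments: [DCTe, DCTl], parameter: apical_PK, change: null, note: "no change"}
  - {segments: [DCTl], parameter: ENaC, change: 0.17, note: "late DCT carries ENaC"}
  - {segments: [DCTe, DCTl], parameter: apical_Pf, change: 0.50}
  - {segments: [DCTe, DCTl], parameter: para_PNa, change: 0.30}
  - {segments: [DCTe, DCTl], parameter: para_PCl, change: 0.30}
  # connecting tubule
  - {segments: [CNT], parameter: length, change: null, note: "no change"}
  - {segments: [CNT], parameter: apical_Pf, change: 0.20}
  - {segments: [CNT], parameter: para_PNa, change: 0.30}
  - {segments: [CNT], parameter: para_PCl, change: 0.30}
  # cortical collecting duct: no change
  - {segments: [CCD], parameter: length, change: null, note: "no change"}
  # outer-medullary collecting duct
  - {segments: [OMCD], parameter: length, change: null, note: "no change"}
  - {segments: [OMCD], parameter: apical_PNa, change: -0.20}
  - {segments: [OMCD], parameter: apical_PCl, change: -0.20}
  # inner-medullary collecting duct
  - {segments: [IMCD], parameter: length, change: null, note: "no change"}
  - {segments: [IMCD], parameter: NHE, change: 2.00}
  - {segments: [IMCD], parameter: NKA, change: 0.20}
  - {segments: [IMCD], parameter: HKA, change: 0.50}
  - {segments: [IMCD], parameter: para_PNa, change: -0.25}
  - {segments: [IMCD], parameter: apical_Pf, change: 0.50}
  - {segments: [IMCD], parameter: apical_PK, change: 1.50}
  - {segments: [IMCD], parameter: para_PK, change: 2.00}
  - {segments: [IMCD], parameter: para_PCl, change: 1.00}
  - {segments: [IMCD], parameter: KCC, change: 3.00}
  - {segments: [IMCD], parameter: NKCC, change: 0.50}
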