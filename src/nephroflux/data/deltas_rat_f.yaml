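# Male-rat -> female-rat parameter differences (relative changes).
# Rows with change: null are printed "no change" entries kept for
# completeness.  Single-valued length/diameter rows apply the same factor
# to both; slashed rows are split into separate length and diameter rows.
column: rat_male_to_female
deltas:
  - {parameter: sngfr, change: -0.20}
  - {parameter: plasma_K, change: -0.10}
  # proximal tubule (convoluted + straight)
  - {segments: [PCT, S3], parameter: length, change: -0.20}
  - {segments: [PCT, S3], parameter: diameter, change: -0.20}
  - {segments: [PCT, S3], parameter: NHE3, change: -0.17}
  - {segments: [PCT], parameter: SGLT2, change: 1.50}
  - {segments: [PCT, S3], parameter: NaPi, change: -0.25}
  - {segments: [PCT, S3], parameter: para_PNa, change: -0.60}
  - {segments: [PCT, S3], parameter: para_PCl, change: -0.60}
  - {segments: [PCT, S3], parameter: apical_Pf, change: -0.36}
  # short descending limb
  - {segments: [SDL], parameter: length, change: -0.15}
  - {segments: [SDL], parameter: diameter, change: -0.15}
  # thick ascending limb
  - {segments: [mTAL, cTAL], parameter: length, change: -0.15}
  - {segments: [mTAL, cTAL], parameter: diameter, change: -0.15}
  - {segments: [mTAL, cTAL], parameter: NKA, change: 1.00}
  - {segments: [mTAL, cTAL], parameter: NHE, change: -0.20}
  - {segments: [mTAL, cTAL], parameter: NaPi, change: -0.20}
  - {segments: [mTAL, cTAL], parameter: NKCC2, change: 1.00}
  - {segments: [mTAL, cTAL], parameter: KCC4, change: 0.50}
  - {segments: [mTAL, cTAL], parameter: para_PNa, change: -0.10}
  - {segments: [mTAL, cTAL], parameter: para_PCl, change: -0.10}
  # distal convoluted tubule
  - {segments: [DCTe, DCTl], parameter: length, change: -0.15}
  - {segments: [DCTe, DCTl], parameter: diameter, change: -0.15}
  - {segments: [DCTe, DCTl], parameter: NCC, change: 1.00}
  - {segments: [DCTe, DCTl], parameter: NKA, change: 1.00}
  - {segments: [DCTe, DCTl], parameter: apical_PK, change: null, note: "no change"}
  - {segments: [DCTl], parameter: ENaC, change: 1.00, note: "late DCT carries ENaC"}
  - {segments: [DCTe, DCTl], parameter: apical_Pf, change: 1.00}
  - {segments: [DCTe, DCTl], parameter: para_PNa, change: 0.40}
  - {segments: [DCTe, DCTl], parameter: para_PCl, change: 0.40}
  - {segments: [DCTe, DCTl], parameter: NHE, change: -0.15}
  - {segments: [DCTe, DCTl], parameter: NaPi, change: -0.15}
  # connecting tubule
  - {segments: [CNT], parameter: length, change: -0.15}
  - {segments: [CNT], parameter: diameter, change: -0.15}
  - {segments: [CNT], parameter: apical_PK, change: null, note: "no change"}
  - {segments: [CNT], parameter: HKA, change: null, note: "no change"}
  - {segments: [CNT], parameter: apical_Pf, change: 0.50}
  - {segments: [CNT], parameter: para_PNa, change: 0.40}
  - {segments: [CNT], parameter: para_PCl, change: 0.40}
  - {segments: [CNT], parameter: NHE, change: -0.10}
  - {segments: [CNT], parameter: NaPi, change: -0.10}
  - {segments: [CNT], parameter: NKA, change: 1.00}
  - {segments: [CNT], parameter: ENaC, change: 0.30}
  # cortical collecting duct
  - {segments: [CCD], parameter: length, change: -0.15}
  - {segments: [CCD], parameter: diameter, change: -0.15}
  - {segments: [CCD], parameter: HKA, change: null, note: "no change"}
  - {segments: [CCD], parameter: apical_Pf, change: 1.00}
  - {segments: [CCD], parameter: apical_PK, change: -0.30}
  - {segments: [CCD], parameter: para_PNa, change: 0.40}
  - {segments: [CCD], parameter: para_PCl, change: 0.40}
  - {segments: [CCD], parameter: NHE, change: -0.10}
  - {segments: [CCD], parameter: NaPi, change: -0.10}
  - {segments: [CCD], parameter: NKA, change: 0.50}
  - {segments: [CCD], parameter: ENaC, change: 0.50}
  # outer-medullary collecting duct
  - {segments: [OMCD], parameter: length, change: -0.15}
  - {segments: [OMCD], parameter: diameter, change: -0.15}
  - {segments: [OMCD], parameter: HKA, change: null, note: "no change"}
  - {segments: [OMCD], parameter: apical_Pf, change: 1.00}
  - {segments: [OMCD], parameter: apical_PK, change: 0.20}
  - {segments: [OMCD], parameter: apical_PNa, change: null, note: "no change"}
  - {segments: [OMCD], parameter: apical_PCl, change: null, note: "no change"}
  - {segments: [OMCD], parameter: NHE, change: -0.10}
  - {segments: [OMCD], parameter: NaPi, change: -0.10}
  - {segments: [OMCD], parameter: NKA, change: 0.10}
  - {segments: [OMCD], parameter: ENaC, change: 0.20}
  # inner-medullary collecting duct
  - {segments: [IMCD], parameter: length, change: -0.15}
  - {segments: [IMCD], parameter: diameter, change: -0.15}
  - {segments: [IMCD], parameter: NHE, change: null, note: "no change"}
  - {segments: [IMCD], parameter: NKA, change: 0.20}
  - {segments: [IMCD], parameter: HKA, change: 0.50}
  - {segments: [IMCD], parameter: para_PNa, change: -0.50}
  - {segments: [IMCD], parameter: apical_Pf, change: 1.00}
  - {segments: [IMCD], parameter: apical_PNa, change: -0.50}
  - {segments: [IMCD], parameter: apical_PK, change: 1.00}
  - {segments: [IMCD], parameter: para_PK, change: null, note: "no change"}
  - {segments: [IMCD], parameter: para_PCl, change: -0.50}
  - {segments: [IMCD], parameter: KCC, change: 0.20}
  - {segments: [IMCD], parameter: NKCC, change: -0.30}
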