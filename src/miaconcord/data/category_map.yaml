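# Default mapping of ICD-10 codes to the five major cause-of-death categories
# used in MIA/CDA concordance analyses.
#
# Keys may be chapter ids (Roman numerals), block ids or category ranges
# ("A30-A49", "C00-C97"), or three-character categories ("J15").  Resolution
# order: category3 entry > block/range entry (narrowest wins) > chapter entry
# > fallback.  Categorisation follows the clinical nature of the condition,
# not strictly the ICD chapter: infection-caused conditions coded outside
# chapter I (pneumonia, CNS infection, peritonitis, pyelonephritis) count as
# infectious diseases.
fallback: other_diseases
categories:
  "I": infectious_diseases          # A00-B99, certain infectious and parasitic diseases
  "C00-C97": malignant_tumors       # chapter II malignant range (D00-D48 stay "other")
  "XVII": congenital_malformations  # Q00-Q99
  "G00-G09": infectious_diseases    # inflammatory (infective) diseases of the CNS
  "J09-J18": infectious_diseases    # influenza and pneumonia
  "J20-J22": infectious_diseases    # other acute lower respiratory infections
  "K65-K67": infectious_diseases    # diseases of peritoneum (peritonitis)
  "N10-N16": infectious_diseases    # renal tubulo-interstitial diseases (pyelonephritis)
  "R95-R99": nonconclusive          # ill-defined and unknown causes of mortality
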