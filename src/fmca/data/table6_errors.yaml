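# Published worst-case feature errors (degrees) and maximum fuzzy-result
# errors (normalized scale) for the three target tests, as reported for the
# original sensor system. The feature-error column is not derivable from the
# landmark-error table with a single closed form, so it is carried as input
# to the grade-resolution arithmetic rather than recomputed.
T1:
  feature_errors_deg:
    F_Va: 23.382
  max_fuzzy_error: 0.104
T2:
  feature_errors_deg:
    F_Va: 14.432
    F_M_1: 14.432
    F_M_2: 23.382
    F_M_3: 14.432
    F_M_4: 23.382
    F_M_5: 7.81
    F_M_6: 6.222
    F_M_7: 2.934
    F_M_8: 6.222
    F_M_9: 4.52
  max_fuzzy_error: 0.128
T3:
  feature_errors_deg:
    F_Vb_1: 14.432
    F_Vb_2: 16.0
  max_fuzzy_error: 0.081
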