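# Kinect V2 landmark tracking errors and anthropometry used for the
# worst-case sensitivity analysis. Landmark errors are "mean (sd)" in cm;
# direct angular error entries are in degrees; segment lengths in cm
# (40-year-old Asian female reference anthropometry).
landmark_errors:
  shoulder: {mean_cm: 1.0, sd_cm: 1.0}
  elbow: {mean_cm: 2.0, sd_cm: 1.0}
  wrist: {mean_cm: 2.0, sd_cm: 1.0}
  spine_shoulder: {mean_cm: 1.0, sd_cm: 1.0}
  spine_mid: {mean_cm: 1.0, sd_cm: 1.0}
rotation_errors_deg:
  shoulder_internal_rotation: 16.0
segment_lengths_cm:
  upper_arm: 27.2
  lower_arm: 29.4
  torso: 90.1
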