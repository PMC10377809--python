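participant_id,age_y,gender,tfbut_s,baseline_sebr,baseline_incomplete_pct,baseline_cv_pct,baseline_exposure_pct,display_sebr,display_incomplete_pct,display_cv_pct,display_exposure_pct,hardcopy_sebr,hardcopy_incomplete_pct,hardcopy_cv_pct,hardcopy_exposure_pct
P1,44,M,10,19,39.3,48.7,8.0,5,0,62.6,38.9,3,0,93.4,34.1
P2,29,F,12,31,21.1,46.1,0.0,18,15.3,57.3,0.0,16,29.0,57.2,1.8
P3,70,M,6,28,68.6,56.4,6.0,5,20,89.9,66.7,2,26.0,108.4,75.5
P4,69,F,4,15,46.0,55.9,42.1,5,26.0,77.7,70.0,5,26.0,48.2,66.7
P5,44,M,10,22,51.9,45.5,6.8,18,36.0,27.7,0.0,21,6.9,33.7,0.0
P6,45,F,5,4,0,130.5,56.2,21,13.8,46.0,6.8,18,23.0,101.9,7.0
P7,41,M,5,32,38.0,67.5,13.0,3,34.3,80.5,59.2,4,0,84.7,83.3
P8,74,F,4,24,41.3,54.1,8.8,16,6.9,49.2,12.1,18,0,44.9,15.8
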