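measure_id,age_min,age_max,mean,sd
cvlt_total,35,44,52.0,10.0
cvlt_total,45,54,50.0,10.0
cvlt_total,55,64,47.0,10.0
cvlt_total,65,74,44.0,10.0
cvlt_total,75,84,40.0,10.0
cvlt_ldfr,35,44,11.5,3.0
cvlt_ldfr,45,54,11.0,3.0
cvlt_ldfr,55,64,10.0,3.2
cvlt_ldfr,65,74,9.0,3.2
cvlt_ldfr,75,84,8.0,3.2
tmt_b,35,44,58.0,20.0
tmt_b,45,54,65.0,24.0
tmt_b,55,64,75.0,28.0
tmt_b,65,74,90.0,35.0
tmt_b,75,84,110.0,45.0
cw_inhibition,35,44,50.0,11.0
cw_inhibition,45,54,53.0,12.0
cw_inhibition,55,64,57.0,13.0
cw_inhibition,65,74,63.0,15.0
cw_inhibition,75,84,70.0,17.0
digit_span,35,44,17.0,4.0
digit_span,45,54,17.0,4.0
digit_span,55,64,16.0,4.0
digit_span,65,74,16.0,4.0
digit_span,75,84,15.0,4.0
tmt_a,35,44,26.0,9.0
tmt_a,45,54,29.0,10.0
tmt_a,55,64,33.0,11.0
tmt_a,65,74,38.0,13.0
tmt_a,75,84,45.0,15.0
boston_naming,35,44,56.0,3.0
boston_naming,45,54,56.0,3.0
boston_naming,55,64,55.0,3.5
boston_naming,65,74,54.0,4.0
boston_naming,75,84,53.0,4.5
block_design,35,44,42.0,11.0
block_design,45,54,39.0,11.0
block_design,55,64,35.0,11.0
block_design,65,74,31.0,10.0
block_design,75,84,27.0,10.0
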