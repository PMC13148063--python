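calculator,outcome,sex,variant,race_arm,term,coefficient
PCE,ascvd,female,base,white,_intercept_,0.0
PCE,ascvd,female,base,white,ln_age,-29.799
PCE,ascvd,female,base,white,ln_age_sq,4.884
PCE,ascvd,female,base,white,ln_tc,13.540
PCE,ascvd,female,base,white,ln_age_x_ln_tc,-3.114
PCE,ascvd,female,base,white,ln_hdl,-13.578
PCE,ascvd,female,base,white,ln_age_x_ln_hdl,3.149
PCE,ascvd,female,base,white,ln_sbp_tx,2.019
PCE,ascvd,female,base,white,ln_sbp_untx,1.957
PCE,ascvd,female,base,white,smoker,7.574
PCE,ascvd,female,base,white,ln_age_x_smoker,-1.665
PCE,ascvd,female,base,white,diabetes,0.661
PCE,ascvd,female,base,white,_mean_lp_,-29.18
PCE,ascvd,female,base,white,_s0_,0.9665
PCE,ascvd,female,base,black,_intercept_,0.0
PCE,ascvd,female,base,black,ln_age,17.114
PCE,ascvd,female,base,black,ln_tc,0.940
PCE,ascvd,female,base,black,ln_hdl,-18.920
PCE,ascvd,female,base,black,ln_age_x_ln_hdl,4.475
PCE,ascvd,female,base,black,ln_sbp_tx,29.291
PCE,ascvd,female,base,black,ln_age_x_ln_sbp_tx,-6.432
PCE,ascvd,female,base,black,ln_sbp_untx,27.820
PCE,ascvd,female,base,black,ln_age_x_ln_sbp_untx,-6.087
PCE,ascvd,female,base,black,smoker,0.691
PCE,ascvd,female,base,black,diabetes,0.874
PCE,ascvd,female,base,black,_mean_lp_,86.61
PCE,ascvd,female,base,black,_s0_,0.9533
PCE,ascvd,male,base,white,_intercept_,0.0
PCE,ascvd,male,base,white,ln_age,12.344
PCE,ascvd,male,base,white,ln_tc,11.853
PCE,ascvd,male,base,white,ln_age_x_ln_tc,-2.664
PCE,ascvd,male,base,white,ln_hdl,-7.990
PCE,ascvd,male,base,white,ln_age_x_ln_hdl,1.769
PCE,ascvd,male,base,white,ln_sbp_tx,1.797
PCE,ascvd,male,base,white,ln_sbp_untx,1.764
PCE,ascvd,male,base,white,smoker,7.837
PCE,ascvd,male,base,white,ln_age_x_smoker,-1.795
PCE,ascvd,male,base,white,diabetes,0.658
PCE,ascvd,male,base,white,_mean_lp_,61.18
PCE,ascvd,male,base,white,_s0_,0.9144
PCE,ascvd,male,base,black,_intercept_,0.0
PCE,ascvd,male,base,black,ln_age,2.469
PCE,ascvd,male,base,black,ln_tc,0.302
PCE,ascvd,male,base,black,ln_hdl,-0.307
PCE,ascvd,male,base,black,ln_sbp_tx,1.916
PCE,ascvd,male,base,black,ln_sbp_untx,1.809
PCE,ascvd,male,base,black,smoker,0.549
PCE,ascvd,male,base,black,diabetes,0.645
PCE,ascvd,male,base,black,_mean_lp_,19.54
PCE,ascvd,male,base,black,_s0_,0.8954
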