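calculator,outcome,sex,variant,race_arm,term,coefficient
PREVENT,overall_cvd,female,hba1c,,hba1c_dm,0.145
PREVENT,overall_cvd,female,hba1c,,hba1c_nodm,0.118
PREVENT,overall_cvd,male,hba1c,,hba1c_dm,0.155
PREVENT,overall_cvd,male,hba1c,,hba1c_nodm,0.125
PREVENT,ascvd,female,hba1c,,hba1c_dm,0.135
PREVENT,ascvd,female,hba1c,,hba1c_nodm,0.105
PREVENT,ascvd,male,hba1c,,hba1c_dm,0.140
PREVENT,ascvd,male,hba1c,,hba1c_nodm,0.110
PREVENT,heart_failure,female,hba1c,,hba1c_dm,0.160
PREVENT,heart_failure,female,hba1c,,hba1c_nodm,0.130
PREVENT,heart_failure,male,hba1c,,hba1c_dm,0.170
PREVENT,heart_failure,male,hba1c,,hba1c_nodm,0.135
PREVENT,overall_cvd,female,adi,,cadi_decile,0.0235
PREVENT,overall_cvd,male,adi,,cadi_decile,0.0220
PREVENT,ascvd,female,adi,,cadi_decile,0.0245
PREVENT,ascvd,male,adi,,cadi_decile,0.0230
PREVENT,heart_failure,female,adi,,cadi_decile,0.0520
PREVENT,heart_failure,male,adi,,cadi_decile,0.0500
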