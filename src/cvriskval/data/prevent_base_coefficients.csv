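calculator,outcome,sex,variant,race_arm,term,coefficient
PREVENT,overall_cvd,female,base,,_intercept_,-3.307728
PREVENT,overall_cvd,female,base,,cage,0.7939329
PREVENT,overall_cvd,female,base,,cnhdl,0.0305239
PREVENT,overall_cvd,female,base,,chdl,-0.1606857
PREVENT,overall_cvd,female,base,,csbp_lt110,-0.2394003
PREVENT,overall_cvd,female,base,,csbp_ge110,0.3600781
PREVENT,overall_cvd,female,base,,diabetes,0.8667604
PREVENT,overall_cvd,female,base,,smoker,0.5360739
PREVENT,overall_cvd,female,base,,cegfr_lt60,0.6045917
PREVENT,overall_cvd,female,base,,cegfr_ge60,0.0433769
PREVENT,overall_cvd,female,base,,bptx,0.3151672
PREVENT,overall_cvd,female,base,,statin,-0.1477655
PREVENT,overall_cvd,female,base,,bptx_x_csbp_ge110,-0.0663612
PREVENT,overall_cvd,female,base,,statin_x_cnhdl,0.1197879
PREVENT,overall_cvd,female,base,,cage_x_cnhdl,-0.0819715
PREVENT,overall_cvd,female,base,,cage_x_chdl,0.0306769
PREVENT,overall_cvd,female,base,,cage_x_csbp_ge110,-0.1082778
PREVENT,overall_cvd,female,base,,cage_x_diabetes,-0.2715682
PREVENT,overall_cvd,female,base,,cage_x_smoker,-0.1767086
PREVENT,overall_cvd,female,base,,cage_x_cegfr_lt60,-0.1181291
PREVENT,overall_cvd,male,base,,_intercept_,-3.031168
PREVENT,overall_cvd,male,base,,cage,0.7688528
PREVENT,overall_cvd,male,base,,cnhdl,0.0736174
PREVENT,overall_cvd,male,base,,chdl,-0.0954431
PREVENT,overall_cvd,male,base,,csbp_lt110,-0.4347345
PREVENT,overall_cvd,male,base,,csbp_ge110,0.3362658
PREVENT,overall_cvd,male,base,,diabetes,0.7692857
PREVENT,overall_cvd,male,base,,smoker,0.4386871
PREVENT,overall_cvd,male,base,,cegfr_lt60,0.5378979
PREVENT,overall_cvd,male,base,,cegfr_ge60,0.0164827
PREVENT,overall_cvd,male,base,,bptx,0.2888790
PREVENT,overall_cvd,male,base,,statin,-0.1337349
PREVENT,overall_cvd,male,base,,bptx_x_csbp_ge110,-0.0475924
PREVENT,overall_cvd,male,base,,statin_x_cnhdl,0.1502730
PREVENT,overall_cvd,male,base,,cage_x_cnhdl,-0.0517874
PREVENT,overall_cvd,male,base,,cage_x_chdl,0.0191169
PREVENT,overall_cvd,male,base,,cage_x_csbp_ge110,-0.1049477
PREVENT,overall_cvd,male,base,,cage_x_diabetes,-0.2251948
PREVENT,overall_cvd,male,base,,cage_x_smoker,-0.0895067
PREVENT,overall_cvd,male,base,,cage_x_cegfr_lt60,-0.1543702
PREVENT,ascvd,female,base,,_intercept_,-3.819975
PREVENT,ascvd,female,base,,cage,0.7198830
PREVENT,ascvd,female,base,,cnhdl,0.1176967
PREVENT,ascvd,female,base,,chdl,-0.1511850
PREVENT,ascvd,female,base,,csbp_lt110,-0.0835358
PREVENT,ascvd,female,base,,csbp_ge110,0.3592852
PREVENT,ascvd,female,base,,diabetes,0.8348585
PREVENT,ascvd,female,base,,smoker,0.4831078
PREVENT,ascvd,female,base,,cegfr_lt60,0.4864619
PREVENT,ascvd,female,base,,cegfr_ge60,0.0397779
PREVENT,ascvd,female,base,,bptx,0.2265309
PREVENT,ascvd,female,base,,statin,-0.0592374
PREVENT,ascvd,female,base,,bptx_x_csbp_ge110,-0.0395762
PREVENT,ascvd,female,base,,statin_x_cnhdl,0.0844423
PREVENT,ascvd,female,base,,cage_x_cnhdl,-0.0567839
PREVENT,ascvd,female,base,,cage_x_chdl,0.0325692
PREVENT,ascvd,female,base,,cage_x_csbp_ge110,-0.1035985
PREVENT,ascvd,female,base,,cage_x_diabetes,-0.2417542
PREVENT,ascvd,female,base,,cage_x_smoker,-0.1671492
PREVENT,ascvd,female,base,,cage_x_cegfr_lt60,-0.1401688
PREVENT,ascvd,male,base,,_intercept_,-3.500655
PREVENT,ascvd,male,base,,cage,0.7099847
PREVENT,ascvd,male,base,,cnhdl,0.1658663
PREVENT,ascvd,male,base,,chdl,-0.1144285
PREVENT,ascvd,male,base,,csbp_lt110,-0.2837212
PREVENT,ascvd,male,base,,csbp_ge110,0.3239977
PREVENT,ascvd,male,base,,diabetes,0.7189597
PREVENT,ascvd,male,base,,smoker,0.3956973
PREVENT,ascvd,male,base,,cegfr_lt60,0.3690075
PREVENT,ascvd,male,base,,cegfr_ge60,0.0203619
PREVENT,ascvd,male,base,,bptx,0.2036522
PREVENT,ascvd,male,base,,statin,-0.0865581
PREVENT,ascvd,male,base,,bptx_x_csbp_ge110,-0.0322916
PREVENT,ascvd,male,base,,statin_x_cnhdl,0.1145630
PREVENT,ascvd,male,base,,cage_x_cnhdl,-0.0300005
PREVENT,ascvd,male,base,,cage_x_chdl,0.0232747
PREVENT,ascvd,male,base,,cage_x_csbp_ge110,-0.0927024
PREVENT,ascvd,male,base,,cage_x_diabetes,-0.2018525
PREVENT,ascvd,male,base,,cage_x_smoker,-0.0970527
PREVENT,ascvd,male,base,,cage_x_cegfr_lt60,-0.1217081
PREVENT,heart_failure,female,base,,_intercept_,-4.310409
PREVENT,heart_failure,female,base,,cage,0.8998235
PREVENT,heart_failure,female,base,,csbp_lt110,-0.4559771
PREVENT,heart_failure,female,base,,csbp_ge110,0.3576505
PREVENT,heart_failure,female,base,,diabetes,1.0383460
PREVENT,heart_failure,female,base,,smoker,0.5839160
PREVENT,heart_failure,female,base,,cbmi_lt30,-0.0072294
PREVENT,heart_failure,female,base,,cbmi_ge30,0.2997706
PREVENT,heart_failure,female,base,,cegfr_lt60,0.7451638
PREVENT,heart_failure,female,base,,cegfr_ge60,0.0557087
PREVENT,heart_failure,female,base,,bptx,0.3534442
PREVENT,heart_failure,female,base,,bptx_x_csbp_ge110,-0.0981511
PREVENT,heart_failure,female,base,,cage_x_csbp_ge110,-0.0946663
PREVENT,heart_failure,female,base,,cage_x_diabetes,-0.3581041
PREVENT,heart_failure,female,base,,cage_x_smoker,-0.1159453
PREVENT,heart_failure,female,base,,cage_x_cbmi_ge30,-0.0038780
PREVENT,heart_failure,female,base,,cage_x_cegfr_lt60,-0.1884289
PREVENT,heart_failure,male,base,,_intercept_,-3.946391
PREVENT,heart_failure,male,base,,cage,0.8972642
PREVENT,heart_failure,male,base,,csbp_lt110,-0.6811466
PREVENT,heart_failure,male,base,,csbp_ge110,0.3634461
PREVENT,heart_failure,male,base,,diabetes,0.9237760
PREVENT,heart_failure,male,base,,smoker,0.5023736
PREVENT,heart_failure,male,base,,cbmi_lt30,-0.0485841
PREVENT,heart_failure,male,base,,cbmi_ge30,0.3726929
PREVENT,heart_failure,male,base,,cegfr_lt60,0.6926917
PREVENT,heart_failure,male,base,,cegfr_ge60,0.0251827
PREVENT,heart_failure,male,base,,bptx,0.2980922
PREVENT,heart_failure,male,base,,bptx_x_csbp_ge110,-0.0497731
PREVENT,heart_failure,male,base,,cage_x_csbp_ge110,-0.1289201
PREVENT,heart_failure,male,base,,cage_x_diabetes,-0.3040924
PREVENT,heart_failure,male,base,,cage_x_smoker,-0.1401688
PREVENT,heart_failure,male,base,,cage_x_cbmi_ge30,0.0068126
PREVENT,heart_failure,male,base,,cage_x_cegfr_lt60,-0.1797778
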