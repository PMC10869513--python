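experiment,role,hrt_d,ts,vs,cod_tot,cod_sol,tn_pct_ts,tp_pct_ts,nh4_n,vfa_cod,ts_sd,vs_sd,cod_tot_sd,cod_sol_sd,tn_pct_ts_sd,tp_pct_ts_sd,nh4_n_sd,vfa_cod_sd
Exp1,feed,20,32.2,31.1,37.3,5.3,3.4,0.31,,,1.8,1.7,3.5,0.9,0.4,0.03,,
Exp1,digestate,20,11.8,9.0,11.4,0.5,15.3,1.66,1.02,0.21,3.5,2.2,1.4,0.1,3.5,0.65,0.18,0.02
Exp2,feed,20,32.1,31.1,40.4,2.8,3.8,0.25,,,2.2,2.1,5.0,0.6,0.7,0.04,,
Exp2,digestate,20,12.5,9.5,12.4,0.5,15.3,1.31,1.09,0.22,2.9,1.6,1.2,0.1,2.6,0.55,0.24,0.03
Exp3,feed,40,67.4,64.2,76.2,14.1,4.1,0.4,,,1.8,1.7,7.9,2.2,0.3,0.1,,
Exp3,digestate,40,15.7,12.1,14.3,0.8,11.5,2.9,0.91,0.29,1.8,1.7,1.9,0.3,1.3,0.4,0.18,0.04
Exp4,feed,40,63.8,61.6,80.1,15.7,4.4,0.5,,,3.5,4.5,6.9,2.3,0.2,0.1,,
Exp4,digestate,40,21.2,16.2,19.5,0.8,10.1,3.2,0.99,0.27,2.9,2.8,2.7,0.2,1.2,0.3,0.1,0.05
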