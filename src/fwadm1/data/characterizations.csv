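stream,ts,vs,cod_tot,cod_sol,carb_tot,carb_sol,prot_tot,prot_sol,lipids,starch,lignocellulosics,ts_sd,vs_sd,cod_tot_sd,cod_sol_sd,carb_tot_sd,carb_sol_sd,prot_tot_sd,prot_sol_sd,lipids_sd,starch_sd,lignocellulosics_sd
raw_fw,220,209,249,69,119,41,35,16,8,63,40,16,15,21,6,10,3,2,2,1,7,3
raw_solid_residue,185,178,212,32,93,19,27,8,8,60,39,15,14,20,3,9,2,2,1,1,6,4
raw_liquid_extract,35,31,37,36,26,22,8,8,0,3,1,2,2,4,4,3,2,1,1,0,1,1
pretreated_solid_residue,116,112,151,40,63,20,19,11,8,31,30,8,8,14,4,6,2,2,1,1,3,3
pretreated_liquid_extract,104,97,98,71,56,46,16,16,0,7,9,8,7,10,7,6,5,1,2,0,1,1
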