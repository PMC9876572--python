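cell_type,group,head_l,head_r,head_m,sg0_l,sg0_r,sg1_l,sg1_r,sg2_l,sg2_r,sg3_l,sg3_r,pyg_l,pyg_r,pyg_m
MUSac-notA,acicular,0,0,0,0,0,2,2,2,2,2,2,0,0,0
MUSac-notP,acicular,0,0,0,0,0,2,2,2,2,2,2,0,0,0
MUSac-notM,acicular,0,0,0,0,0,2,2,2,2,2,2,0,0,0
MUSac-notDo,acicular,0,0,0,0,0,0,0,1,0,0,0,0,0,0
MUSac-neuAV,acicular,0,0,0,0,0,2,2,3,3,3,3,0,0,0
MUSac-neuPD,acicular,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSac-neuPV,acicular,0,0,0,0,0,2,2,3,3,2,2,0,0,0
MUSac-neuDy,acicular,0,0,0,0,0,0,0,1,1,1,1,0,0,0
MUSac-neuDx,acicular,0,0,0,0,0,0,0,2,2,2,2,0,0,0
MUSac-neuDach,acicular,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSac-neure,acicular,0,0,0,0,0,1,1,2,2,1,1,0,0,0
MUSac-i,acicular,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSobA-re,anterior_oblique,0,0,0,0,0,6,5,7,7,7,7,0,0,0
MUSobA-arc,anterior_oblique,0,0,0,0,0,2,2,4,4,3,3,0,0,0
MUSobA-mpp,anterior_oblique,0,0,0,0,0,1,1,2,2,3,3,0,0,0
MUSobA-mlpp,anterior_oblique,0,0,0,0,0,0,0,2,2,0,0,0,0,0
MUSobA-lpp,anterior_oblique,0,0,0,0,0,1,1,2,2,2,2,0,0,0
MUSobA-trans,anterior_oblique,0,0,0,0,0,1,1,2,2,2,2,0,0,0
MUSobP-notD,posterior_oblique,0,0,0,0,0,4,4,5,5,5,5,0,0,0
MUSobP-neuDlong,posterior_oblique,0,0,0,0,0,1,1,2,2,2,1,0,0,0
MUSobP-neuDprox,posterior_oblique,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSobP-neuDdist,posterior_oblique,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSobP-neuV,posterior_oblique,0,0,0,0,0,5,5,7,7,7,7,0,0,0
MUSobP-notV,posterior_oblique,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSobP-M,posterior_oblique,0,0,0,0,0,0,0,1,1,1,1,0,0,0
MUSobP-noty,posterior_oblique,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSobP,posterior_oblique,0,0,0,2,2,0,0,0,0,0,0,0,0,0
MUSobP-i,posterior_oblique,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSob,posterior_oblique,0,0,0,1,1,0,0,0,0,0,0,0,0,0
MUSchae-notDob,chaetal,0,0,0,0,0,3,3,3,3,3,3,0,0,0
MUSchae-notD,chaetal,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSchae-notDn,chaetal,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSchae-notA,chaetal,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSchae-notAac,chaetal,0,0,0,0,0,4,4,4,4,4,4,0,0,0
MUSchae-notAre,chaetal,0,0,0,0,0,0,0,1,1,1,1,0,0,0
MUSchae-neuVob,chaetal,0,0,0,0,0,2,2,3,3,2,2,0,0,0
MUSchae-neuDac,chaetal,0,0,0,0,0,4,4,5,5,5,5,0,0,0
MUSchae-neuAVo,chaetal,0,0,0,0,0,2,2,3,3,3,3,0,0,0
MUSchae-neuAVt,chaetal,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUSchae-Are,chaetal,0,0,0,0,0,1,1,1,1,1,1,0,0,0
MUStrans,transverse,0,0,0,4,5,5,5,9,9,8,9,4,4,0
MUSlongD,longitudinal,0,0,0,11,15,13,15,10,10,7,7,0,0,0
MUSlongV,longitudinal,9,8,1,7,4,8,12,11,8,7,7,1,1,0
MUSax,longitudinal,0,0,0,0,0,4,4,1,1,1,1,0,0,0
MUSring-pyg,digestive,0,0,0,0,0,0,0,0,0,0,0,0,0,1
MUSph,digestive,28,30,0,0,0,0,0,0,0,0,0,0,0,0
MUSll,digestive,5,5,0,0,0,0,0,0,0,0,0,0,0,0
MUSant,head,4,4,0,0,0,0,0,0,0,0,0,0,0,0
MUSly,head,3,3,0,0,0,0,0,0,0,0,0,0,0,0
MUSpl,head,2,2,0,0,0,0,0,0,0,0,0,0,0,0
MUSci,head,2,2,0,0,0,0,0,0,0,0,0,0,0,0
MUSch,head,3,3,0,0,0,0,0,0,0,0,0,0,0,0
MUSpx,head,0,0,1,0,0,0,0,0,0,0,0,0,0,0
MUSpr-Vt,head,0,0,1,0,0,0,0,0,0,0,0,0,0,0
MUStri,head,1,1,0,0,0,0,0,0,0,0,0,0,0,0
MUSmed-head,head,1,1,0,0,0,0,0,0,0,0,0,0,0,0
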