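feature,a,n1,c,n2
mod_low_voltage,5,156,16,159
ecs,0,156,2,159
delta_le_1,3,156,32,159
delta_1_2,53,156,62,159
delta_2_3,37,156,49,159
delta_3_4,9,156,9,159
theta_4_5,36,156,63,159
theta_5_6,56,156,40,159
theta_6_8,22,156,15,159
alpha_le_8,28,156,6,159
alpha_8_9,19,156,3,159
alpha_ge_9,17,156,7,159
pdr,42,156,0,159
grda,3,156,5,159
gpds,2,156,14,159
lrda,2,156,1,159
lpds,1,156,4,159
brief_attenuation,0,156,4,159
burst_suppression,0,156,1,159
seizures,0,156,10,159
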