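id,kind,foot,x_mm,y_mm
p_heel_m,pressure,L,-15.0,25.0
p_heel_l,pressure,L,15.0,25.0
p_heel_m2,pressure,L,-18.0,48.0
p_heel_l2,pressure,L,18.0,48.0
p_arch_1,pressure,L,-20.0,100.0
p_arch_2,pressure,L,-15.0,125.0
p_mid_l1,pressure,L,25.0,105.0
p_mid_l2,pressure,L,28.0,130.0
p_met_1,pressure,L,-30.0,180.0
p_met_2,pressure,L,-15.0,186.0
p_met_3,pressure,L,0.0,188.0
p_met_4,pressure,L,16.0,184.0
p_met_5,pressure,L,30.0,176.0
p_toe_hallux,pressure,L,-22.0,232.0
p_toe_2,pressure,L,0.0,238.0
p_toe_3,pressure,L,20.0,228.0
t_hallux,temperature,L,-18.0,230.0
t_met_1,temperature,L,-20.0,178.0
t_met_2,temperature,L,0.0,182.0
t_met_3,temperature,L,22.0,175.0
t_mid,temperature,L,5.0,115.0
t_heel_1,temperature,L,0.0,30.0
t_heel_2,temperature,L,-14.0,45.0
t_heel_3,temperature,L,14.0,45.0
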