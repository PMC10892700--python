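channel,green_lo,green_hi,yellow_lo,yellow_hi
trunk_flexion,-5,20,-10,60
neck_flexion,-5,25,-10,45
upper_arm_flexion_l,-20,20,-60,60
upper_arm_flexion_r,-20,20,-60,60
upper_arm_abduction_l,-10,30,-20,60
upper_arm_abduction_r,-10,30,-20,60
lower_arm_flexion_l,60,100,30,140
lower_arm_flexion_r,60,100,30,140
wrist_flexion_l,-15,15,-30,30
wrist_flexion_r,-15,15,-30,30
wrist_deviation_l,-10,10,-20,20
wrist_deviation_r,-10,10,-20,20
wrist_twist_l,-45,45,-90,90
wrist_twist_r,-45,45,-90,90
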