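segment,mass_fraction,length_fraction,com_fraction_from_proximal,bilateral
hand,0.006,0.108,0.506,1
forearm,0.016,0.146,0.430,1
upper_arm,0.028,0.186,0.436,1
head_neck,0.081,0.182,0.400,0
trunk_upper,0.355,0.218,0.550,0
pelvis,0.142,0.070,0.500,0
thigh,0.100,0.245,0.433,1
shank,0.0465,0.246,0.433,1
foot,0.0145,0.039,0.500,1
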