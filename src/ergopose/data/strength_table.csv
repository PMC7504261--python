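joint,direction,mean_nm,sd_nm,population
elbow,flexion,65,20,combined
elbow,extension,45,15,combined
shoulder,flexion,85,30,combined
shoulder,extension,70,25,combined
torso,extension,210,70,combined
torso,flexion,145,50,combined
hip,extension,230,80,combined
hip,flexion,150,55,combined
knee,extension,190,65,combined
knee,flexion,100,35,combined
ankle,plantarflexion,140,50,combined
ankle,dorsiflexion,45,15,combined
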