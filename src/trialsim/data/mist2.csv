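term_type,name,proportion,value
main,pleural_effusion,0.67,-25.4
main,purulence,0.49,1.8
main,hospital_infection,0.13,-7.0
interaction,pleural_effusion:purulence,0.29,3.5
interaction,pleural_effusion:hospital_infection,0.07,24.4
interaction,purulence:hospital_infection,0.06,-1.6
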