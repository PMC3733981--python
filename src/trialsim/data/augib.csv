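term_type,name,proportion,value
main,outpatient,0.83,0.32
main,shock,0.36,2.83
main,urea,0.55,1.88
main,coagulation,0.13,1.87
interaction,outpatient:shock,0.30,1.07
interaction,outpatient:urea,0.44,1.67
interaction,outpatient:coagulation,0.10,1.97
interaction,shock:urea,0.24,0.71
interaction,shock:coagulation,0.06,0.79
interaction,urea:coagulation,0.09,0.77
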