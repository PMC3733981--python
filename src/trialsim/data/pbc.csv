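term_type,name,proportion,value
main,age,0.51,3.01
main,log_bilirubin,0.50,10.65
main,albumin,0.50,0.58
main,disease_stage,0.73,5.02
interaction,age:log_bilirubin,0.24,1.03
interaction,age:albumin,0.23,1.40
interaction,age:disease_stage,0.38,0.66
interaction,log_bilirubin:albumin,0.18,0.77
interaction,log_bilirubin:disease_stage,0.42,0.45
interaction,albumin:disease_stage,0.32,0.65
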