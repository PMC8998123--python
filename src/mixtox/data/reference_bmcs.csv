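model,chemical,bmc10_uM,bmc50_uM,regression_model
NHBE,HHCB,3.61,42.2,Gamma
NHBE,AHTN,33.5,84.9,Gamma
NHBE,BHT,45.9,103,Logistic
NHBE,G14 Mix,1.25,47.7,Log Logistic
NHBE,NHBE Equi-Mix,8.29,54.0,Weibull
NHBE,NHBE BMC Mix,47.8,94.9,Log Logistic
Zebrafish,BBP,3.29,4.28,Log Logistic
Zebrafish,DBP,2.80,4.27,Log Logistic
Zebrafish,DIBP,3.48,5.32,Logistic
Zebrafish,G14 Mix,46.2,55.4,Log Logistic
Zebrafish,ZF Equi-Mix,3.58,5.36,Gamma
Zebrafish,ZF BMC Mix,3.58,6.41,Weibull
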