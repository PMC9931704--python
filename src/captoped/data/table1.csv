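id,study,population,dose,dose_unit,age_years,weight_kg,sex,serum_creatinine_mg_dl,egfr,source
RF1,1,renal_failure,2.3,mg/kg,5.5,,M,0.61,61,Sinaiko
RF2,1,renal_failure,0.8,mg/kg,3.5,,M,1.8,59,Sinaiko
RF3,1,renal_failure,1.6,mg/kg,9,,M,3.2,20,Sinaiko
RF4,1,renal_failure,1.6,mg/kg,12.5,,M,3.4,26,Sinaiko
RF5,1,renal_failure,1.2,mg/kg,11.5,,M,1.3,83,Sinaiko
RF6,1,renal_failure,2,mg/kg,20,,M,4.2,20,Sinaiko
RS1,2,renal_scarring,12.5,mg,5,18,F,0.28,187,Levy
RS2,2,renal_scarring,20,mg,12,29.6,F,0.56,142,Levy
RS3,2,renal_scarring,16.5,mg,6,24,F,0.35,173,Levy
RS4,2,renal_scarring,23.5,mg,10,34,F,0.67,135,Levy
RS5,2,renal_scarring,46,mg,18,66,M,1.25,83,Levy
RS6,2,renal_scarring,37.5,mg,14,52.8,F,0.58,138,Levy
RS7,2,renal_scarring,37.5,mg,11,53.7,F,0.56,148,Levy
RS8,2,renal_scarring,20,mg,7,29.7,M,0.34,200,Levy
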