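id,study,age_years,dose,dose_unit,auc_obs,auc_pred,auc_ratio,cmax_obs,cmax_pred,cmax_ratio,clf_obs,clf_pred,clf_ratio,clf_unit
RF2,sinaiko,3.5,0.8,mg/kg,1126.50,488.34,0.43,359,238.22,0.66,0.71,1.64,2.29,L/h/kg
RF5,sinaiko,11.5,1.2,mg/kg,768.35,832.62,1.08,520,408.69,0.79,1.56,1.44,0.82,L/h/kg
RF3,sinaiko,9,1.6,mg/kg,1382.10,1568.91,1.14,371,636.97,1.72,1.16,1.02,0.72,L/h/kg
RF4,sinaiko,12.5,1.6,mg/kg,1726.85,1637.16,0.95,569,649.95,1.14,0.93,0.98,0.81,L/h/kg
RF6,sinaiko,20,2,mg/kg,2153.50,2978.25,1.38,719,969.29,1.35,0.09,0.07,0.47,L/h/kg
RF1,sinaiko,5.5,2.3,mg/kg,2299.00,1259.76,0.55,435,585.29,1.35,1.00,1.83,1.82,L/h/kg
RS1,levy,5,12.5,mg,189.40,436,2.30,163,236,1.45,66.00,28.65,0.43,L/h
RS3,levy,6,16.5,mg,503.50,527.44,1.05,547,283.26,0.52,32.77,31.28,0.95,L/h
RS2,levy,12,20,mg,318.80,361,1.13,165,182,1.10,62.74,55.36,0.88,L/h
RS4,levy,10,23.5,mg,221.90,523.00,2.36,100,270.00,2.70,105.90,44.93,0.42,L/h
RS8,levy,7,20,mg,579.80,571.64,0.99,197,301.67,1.53,34.49,34.99,1.01,L/h
RS6,levy,14,37.5,mg,274.50,564.93,2.06,134,278.39,2.08,136.61,66.38,0.49,L/h
RS7,levy,11,37.5,mg,828.40,753.17,0.91,450,384.55,0.85,45.27,49.79,1.09,L/h
RS5,levy,18,46,mg,1082.10,635.37,0.60,385,244.50,0.64,42.51,72.40,1.70,L/h
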