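analyte,tef,c_ng_m3,fbioa_percent,fbioa_percent_display,adi_printed,di_bioa_printed,risk_di_bioa_printed,di_total_printed,risk_di_total_printed,ac_printed,bc_printed,risk_teq_bioa_printed,risk_teq_total_printed
Nap,0.001,0.13,,,0.2564,,,0.0325,,11.49,,,
Acl,0.001,0.07,38.72,38.7,0.2564,0.0068,,0.0175,,11.49,0.03,,
Ace,0.001,0.03,19.58,19.6,0.2564,0.0015,,0.0075,,11.49,0.01,,
Flu,0.001,0.26,17.45,17.4,0.2564,0.0113,,0.0650,,11.49,0.05,,
Phe,0.001,2.30,21.28,21.3,0.2564,0.1224,,0.5750,Risky,11.49,0.49,,
Ant,0.001,0.88,18.72,18.7,0.2564,0.0412,,0.2200,,11.49,0.16,,
FA,0.01,2.96,19.58,19.6,0.0256,0.1449,Risky,0.7400,Risky,1.15,0.58,,Risky
Pyr,0.001,2.24,19.15,19.1,0.2564,0.1072,,0.5600,Risky,11.49,0.43,,
BaA,0.1,4.61,2.77,2.77,0.0026,0.0319,Risky,1.1525,Risky,0.11,0.13,Risky,Risky
Chr,0.01,4.68,6.81,6.81,0.0256,0.0797,Risky,1.1700,Risky,1.15,0.32,,Risky
BbF + BkF,0.2,4.73,3.62,3.62,0.0013,0.0428,Risky,1.1825,Risky,0.06,0.17,Risky,Risky
BaP,1,2.88,5.94,5.94,0.0003,0.0428,Risky,0.7200,Risky,0.01,0.17,Risky,Risky
Ind,0.1,4.88,2.13,2.13,0.0026,0.0259,Risky,1.2200,Risky,0.11,0.10,,Risky
DBahA,1,0.80,4.68,4.68,0.0003,0.0094,Risky,0.2000,Risky,0.01,0.04,Risky,Risky
BghiP,0.01,6.06,2.34,2.34,0.0256,0.0355,Risky,1.5150,Risky,1.15,0.14,,Risky
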