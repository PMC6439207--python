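biochar,fluid,analyte,q_ug_g,fbioa_percent,di_printed_ng_kg_day
W300,gamble,Phe,10,0.7541,0.1056
W300,gamble,Pyr,10,0.7520,0.1053
W300,alf,Phe,10,0.6006,0.0841
W300,alf,Pyr,10,0.5021,0.0703
W500,gamble,Phe,10,0.7472,0.1046
W500,gamble,Pyr,10,0.6233,0.0873
W500,alf,Phe,10,0.6110,0.0855
W500,alf,Pyr,10,0.4658,0.0652
W700,gamble,Phe,10,0.6569,0.0920
W700,gamble,Pyr,10,0.4694,0.0657
W700,alf,Phe,10,0.5479,0.0767
W700,alf,Pyr,10,0.3610,0.0505
WN,gamble,Phe,10,0.7495,0.1049
WN,gamble,Pyr,10,0.7422,0.1039
WN,alf,Phe,10,0.5224,0.0731
WN,alf,Pyr,10,0.6739,0.0944
C300,gamble,Phe,10,1.4870,0.2082
C300,gamble,Pyr,10,1.1273,0.1578
C300,alf,Phe,10,1.3102,0.1834
C300,alf,Pyr,10,1.0855,0.1520
C500,gamble,Phe,10,0.6995,0.0979
C500,gamble,Pyr,10,0.9940,0.1392
C500,alf,Phe,10,0.6110,0.0855
C500,alf,Pyr,10,0.9911,0.1387
C700,gamble,Phe,10,0.4701,0.0658
C700,gamble,Pyr,10,0.5321,0.0745
C700,alf,Phe,10,0.3537,0.0495
C700,alf,Pyr,10,0.5172,0.0724
CN,gamble,Phe,10,1.3340,0.1868
CN,gamble,Pyr,10,0.4299,0.0602
CN,alf,Phe,10,1.2051,0.1687
CN,alf,Pyr,10,0.4065,0.0569
S300,gamble,Phe,10,0.9255,0.1296
S300,gamble,Pyr,10,0.7838,0.1097
S300,alf,Phe,10,0.7448,0.1043
S300,alf,Pyr,10,0.5986,0.0838
S500,gamble,Phe,10,0.7123,0.0997
S500,gamble,Pyr,10,0.5997,0.0840
S500,alf,Phe,10,0.5394,0.0755
S500,alf,Pyr,10,0.3769,0.0528
S700,gamble,Phe,10,0.5127,0.0718
S700,gamble,Pyr,10,0.4791,0.0671
S700,alf,Phe,10,0.3710,0.0519
S700,alf,Pyr,10,0.3374,0.0472
P500,gamble,Phe,10,0.7111,0.0996
P500,gamble,Pyr,10,0.5270,0.0738
P500,alf,Phe,10,0.4961,0.0694
P500,alf,Pyr,10,0.4816,0.0674
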