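biochar,fluid,analyte,q_ug_g,fbioa_percent,di_printed_ng_kg_day
W500,gamble,Phe,10,0.7472,0.1046
W500,gamble,Pyr,10,0.6233,0.0873
W500,gamble,Phe,50,2.6700,1.8690
W500,gamble,Pyr,50,1.1021,0.7714
W500,gamble,Phe,100,1.0969,1.5356
W500,gamble,Pyr,100,1.2169,1.7037
C500,gamble,Phe,10,0.6995,0.0979
C500,gamble,Pyr,10,0.7813,0.1094
C500,gamble,Phe,50,1.4405,1.0084
C500,gamble,Pyr,50,0.5516,0.3861
C500,gamble,Phe,100,1.3398,1.8757
C500,gamble,Pyr,100,0.9940,1.3916
S500,gamble,Phe,10,0.7123,0.0997
S500,gamble,Pyr,10,0.5997,0.0840
S500,gamble,Phe,50,2.2603,1.5822
S500,gamble,Pyr,50,0.7867,0.5507
S500,gamble,Phe,100,1.7200,2.4080
S500,gamble,Pyr,100,0.7007,0.9810
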