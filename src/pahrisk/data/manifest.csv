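filename,description,units,sha256
table1_biochar.csv,"biochar F_bioa at 10 ug/g, two lung fluids","fbioa_percent: %, q_ug_g: ug/g, di_printed_ng_kg_day: ng/kg/day (display)",764045804ad6c636e1707b97f10f454ee6b2d393f1221ae8528d973860c65a29
table2_biochar_loading.csv,biochar F_bioa in Gamble's solution at 10/50/100 ug/g,"fbioa_percent: %, q_ug_g: ug/g, di_printed_ng_kg_day: ng/kg/day (display)",97172462e4b2db7d42071523694fb3f2562fd14d0fc6595f5325f583ed1d4441
pm25_pahs.csv,"PM2.5 analytes: TEF, ambient conc, F_bioa (SELF), printed assessment columns","tef: dimensionless, c_ng_m3: ng/m3, fbioa_percent: % (canonical), *_printed/_display: rounded display values",27a6b20d4c87be7fd51768afdbb837758e57f66e5af1e6efd9cc4b1a98a9b382
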