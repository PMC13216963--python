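acid,pka_original
2-(C6H5-CC-)-C6H4-COMe,27.68
C6H5-CO-CH2-C6H5,27.47
2-(C6H5-CC-)-C6H4-COEt,27.39
C6H5-CO-CH(Et)C6H5,27.32
C6H5-CO-CH(Me)C6H5,26.33
2-indanone,26.07
cyclopentadiene,26.00
MeCO-CH2-COMe,25.18
9-C6H5S-fluorene,25.14
4-MeO-C6H4CH2NO2,24.34
MeCO-CH2-COOEt,24.26
4-CN-C6H4CH2CN,24.32
MeCO-CH2-COOMe,24.14
9-(C6H5-NH-N=)-fluorene,23.94
(EtSO2)2(Et)CH,23.90
9-MeSO2-fluorene,23.49
(EtSO2)2(i-Pr)CH,23.31
9-EtSO2-fluorene,22.92
(EtSO2)2CH2,22.94
9-C6H5SO2-fluorene,22.85
[DBUH]+,22.58
9-COOMe-fluorene,21.93
(C6H5SO2)2CH2,21.85
C6H5-CO-CH2CN,20.95
4-Cl-C6H4-CO-CH2CN,20.10
9-CN-fluorene,20.15
2-NO2-9-Tos-fluorene,19.35
2-NO2-9-(4-Br-C6H4SO2)-fluorene,18.57
"4-Me-2,6-(NO2)2-phenol",17.78
"2-NO2-9-(2,4-Cl2-C6H3SO2)-fluorene",17.82
4-MeO-C6H4CH(CN)2,17.49
4-Me-C6H4CH(CN)2,17.10
9-CF3SO2-fluorene,16.76
C6H5CH(CN)2,16.36
"4-Cl-2,6-(NO2)2-phenol",14.88
4-Cl-C6H4CH(CN)2,14.74
4-CF3-C6H4CH(CN)2,12.00
4-CN-C6H4CH(CN)2,10.23
4-NO2-C6H4CH(CN)2,9.34
4-CF3SO2-C6H4CH(CN)2,8.13
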