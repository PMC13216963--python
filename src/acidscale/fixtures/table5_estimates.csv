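compound,est_mecn,est_dce
9-COOMe-fluorene,54.3,53.6
(4-Me-C6F4)2CHCN,53.5,53.2
(4-Me-C6F4)(C6F5)CHCN,52.5,52.2
9-CN-fluorene,51.9,51.4
(4-H-C6F4)(C6F5)CHCN,51.6,51.2
(4-Cl-C6F4)(C6F5)CHCN,50.8,50.3
"2,3,4,5,6-F5-phenol",50.5,
(2-C10F7)(C6F5)CHCN,50.5,49.9
(2-C10F7)2CHCN,49.6,48.9
9-C6F5-octafluorofluorene,49.2,49.3
(4-NC5F4)(4-CF3-C6F4)NH,48.5,
(4-CF3-C6F4)(C6F5)CHCN,48.3,47.9
"4-C6F5-2,3,5,6-F4-phenol",48.3,
"2,3,4,5,6-Cl5-phenol",48.2,
"2,3,4,5,6-Br5-phenol",48.0,
(C6F5)CH(CN)COOEt,47.9,48.0
4-Me-C6H4-CH(CN)2,47.7,
(2-C10F7)CH(CN)COOEt,47.6,47.6
(4-Cl-C6F4)CH(CN)COOEt,47.5,47.8
(4-NC5F4)2NH,47.3,
"2-Me-4,6-(NO2)2-phenol",47.1,
"2,4-(NO2)2-phenol",46.7,
"4-CF3-2,3,5,6-F4-phenol",46.7,
(4-CF3-C6F4)CH(CN)COOEt,46.1,46.2
(4-NC5F4)CH(CN)COOEt,44.8,45.0
saccharin,44.4,
3-NO2-C6H4SO2NHSO2C6H4-3-Cl,44.4,
4-NO2-C6H4SO2NHSO2C6H4-3-Cl,44.3,
"2-Cl-4,6-(NO2)2-phenol",44.1,
(4-NC5F4)2CHCN,43.2,43.0
Tos2NH,41.6,
Ph-SO2NHSO2-Me,41.5,
bromothymol blue,41.3,41.7
(C6H5SO2)2NH,40.9,
4-MeO-C6H4SO2NHSO2C6H4-4-Cl,40.8,
4-Cl-C6H4SO2NH-Tos,40.6,
bromocresol green,40.5,40.9
HNO3,40.1,39.3
"(2,4,6-(NO2)3-C6H2)2NH",40.0,
HCl,39.7,40.8
4-Cl-C6H4SO2NH-Tos (2),39.7,
(4-Cl-C6H4-SO2)2NH,39.6,
4-Cl-3-NO2C6H3SO2NH-Tos,39.1,
4-NO2-C6H4SO2NHSO2C6H4-4-Cl,38.5,38.1
"(2,3,4,5,6-(CF3)5-C6)2NH",38.0,
4-Cl-3-NO2-C6H3SO2NHSO2C6H4-4-Cl,38.0,
TosOH,37.8,
3-NO2-C6H4SO2NHSO2C6H3-3-NO2-4-Cl,37.0,
H2SO4,36.8,38.4
C6F5SO2NHSO2C6H4-4-Cl,36.7,
(3-NO2-4-Cl-C6H3SO2)2NH,36.6,36.1
C6F5SO2NHSO2C6H3-3-NO2-4-Cl,35.2,
4-NO2-C6H4SO2CH(CN)2,35.0,35.6
Tos-NH-Tf,34.8,
4-Me-C6H4-C(=NTf)-NH-Tf,34.8,
C6H5-C(=NTf)-NH-Tf,34.7,
C6H5SO2NH-Tf,34.5,
HBr,34.3,36.3
4-F-C6H4-C(=NTf)-NH-Tf,34.2,
4-Cl-C6H4-C(=NTf)-NH-Tf,34.1,
(C6F5SO2)2NH,34.0,
CH(CN)3,33.9,34.4
4-Cl-C6H4SO(=NTf)-NH-Tos,33.7,33.8
"2,4,6-Tf3-phenol",33.3,34.2
C(CN)2C(CN)OH,33.2,32.1
4-NO2-C6H4SO2NHTf,32.9,32.9
4-Cl-C6H4SO(=NTf)NHSO2C6H4-4-Cl,32.8,32.9
"2,4-(NO2)2-C6H3SO2OH",32.8,31.8
4-Cl-C6H4SO(=NTf)NHSO2C6H4-4-NO2,32.0,31.7
HI,31.5,33.5
TfOH,31.3,29.6
HClO4,30.1,28.1
styphnic acid,,39.8
pentacyanophenol,,33.2
C6F5CH(Tf)2,,31.7
HB(CN)(CF3)3,,31.5
Ph-TCNP,,31.3
HBF4,,30.8
FSO2OH,,30.6
3-CF3-C6H4-TCNP,,30.2
[C6H5SO(=NTf)]2NH,,29.5
[(C2F5)2PO]2NH,,29.3
"2,4,6-(NO2)3-C6H2SO2OH",,29.4
[C(CN)2C(CN)]2CH2,,29.4
C6H5SO(=NTf)NHTf,,29.2
TfCH(CN)2,,29.3
Br-TCNP,,29.1
[C(CN)2C(CN)]2NH,,28.9
"3,5-(CF3)5-C6H3-TCNP",,28.8
Tf2NH,,28.9
4-Cl-C6H4SO(=NTf)NHTf,,28.6
Cl-TCNP,,28.8
(C3F7SO2)2NH,,28.6
(C4F9SO2)2NH,,28.5
CN-CH2-TCNP,,28.5
(C2F5SO2)2NH,,28.4
CF3-TCNP,,28.1
CF2(CF2SO2)2NH,,27.8
4-NO2-C6H4SO(=NTf)NHTf,,27.5
HB(CN)4,,27.6
(FSO2)3CH,,27.3
Tf2CH(CN),,25.9
"2,3,4,5-tetracyanocyclopentadiene",,25.8
CN-TCNP,,25.6
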