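no,acid,pka_dfb,pka_mecn,pka_dce,class
1,"2,6-(NO2)2-phenol",47.6,16.74,,phenol
2,"4-F-2,6-(NO2)2-phenol",46.7,16.17,,phenol
3,"(4-NC5F4)(C6F5)CHCN",46.1,16.39,50.5,arylacetonitrile
4,"4-NO2-C6H4SO2NHCOC6H4-4-Me",45.6,15.68,,sulfonimide
5,"(4-NC5F4)(2-C10F7)CHCN",45.6,16.01,,arylacetonitrile
6,"(4-CF3-C6F4)2CHCN",45.6,16.12,,arylacetonitrile
7,"3-CF3-C6H4CH(CN)2",44.6,14.70,49.0,arylmalononitrile
8,"4-Me-C6F4CH(CN)2",44.1,13.87,,arylmalononitrile
9,"2,3,4,5,6-(CF3)5-C6CH(CN)COOEt",43.4,13.41,47.8,cyanoester
10,"4-H-C6F4CH(CN)2",43.0,12.98,47.5,arylmalononitrile
11,"C6F5CH(CN)2",42.8,13.01,,arylmalononitrile
12,"2-C10F7CH(CN)2",41.9,12.23,46.3,arylmalononitrile
13,"4-NO2-C6H4CH(CN)2",41.0,11.61,,arylmalononitrile
14,"picric acid",40.8,11.00,45.0,phenol
15,"2,3,4,6-(CF3)4-C6HCH(CN)2",39.9,10.42,44.2,arylmalononitrile
16,"2,3,4,5,6-(CF3)5-phenol",39.9,10.46,,phenol
17,"4-CF3-C6F4CH(CN)2",39.7,10.19,44.2,arylmalononitrile
18,"4-NO2-C6H4SO2NHTos",39.4,10.04,43.3,sulfonimide
19,"2,4-(NO2)2-C6H3CH(CN)2",38.5,9.58,,arylmalononitrile
20,"2,3,4,5,6-(CF3)5-C6CH(CN)2",37.8,8.88,42.2,arylmalononitrile
21,"2,4,6-(SO2OCH2CF2CF2H)3-phenol",36.9,8.14,,phenol
22,"(4-NO2-C6H4-SO2)2NH",36.8,8.15,41.1,sulfonimide
23,"2,4,6-(SO2OCH2CF3)3-phenol",36.6,7.94,,phenol
24,"4-NO2-C6H4SO2NHSO2C6H3-3-NO2-4-Cl",36.5,7.82,40.7,sulfonimide
25,"Me-TCNPD",36.3,7.36,,tetracyanopentadiene
26,"C6F5SO2NHSO2C6H4-4-NO2",35.4,6.60,,sulfonimide
27,"2,4,6-(SO2F)3-phenol",34.7,5.22,39.0,phenol
28,"H-TCNPD",34.7,5.64,,tetracyanopentadiene
29,"NH2-TCNP",33.9,,38.2,tetracyanopropene
30,"2,3,5-(CN)3-cyclopentadiene",33.6,3.65,38.0,cyclopentadiene
31,"4-MeO-C6H4-TCNP",32.0,,36.1,tetracyanopropene
32,"Me-TCNP",32.1,,36.4,tetracyanopropene
33,"3,4-(MeO)2-C6H3-TCNP",32.0,,36.1,tetracyanopropene
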