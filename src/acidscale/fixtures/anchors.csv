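no,acid
1,"2,6-(NO2)2-phenol"
3,"(4-NC5F4)(C6F5)CHCN"
8,"4-Me-C6F4CH(CN)2"
11,"C6F5CH(CN)2"
14,"picric acid"
22,"(4-NO2-C6H4-SO2)2NH"
28,"H-TCNPD"
30,"2,3,5-(CN)3-cyclopentadiene"
33,"3,4-(MeO)2-C6H3-TCNP"
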