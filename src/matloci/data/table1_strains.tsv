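strain_id	karyotype	type_a	type_b
Hm13	di	Type1	Type1
Hm15	di	Type1	Type1
Hm17	di	Type1	Type1
Hm71	di	Type1	Type1
Hm78	di	Type1	Type1
Hm20	di	Type1	Type2
Hm47	di	Type1	Type2
Hm46	di	Type1	Type2
Hm62	di	Type1	Type2
Hm77	di	Type1	Type2
Hm81	di	Type1	Type2
Hm83	di	Type1	Type2
Hm89	di	Type1	Type2
Hm3	di	Type1	Type3
Hm10	di	Type1	Type3
Hm11	di	Type1	Type3
Hm12	di	Type1	Type3
Hm16	di	Type1	Type3
Hm19	di	Type1	Type3
Hm26	di	Type1	Type3
Hm30	di	Type1	Type3
Hm38	di	Type1	Type3
Hm56	di	Type1	Type3
Hm59	di	Type1	Type3
Hm72	di	Type1	Type3
Hm82	di	Type1	Type3
Hm42	di	Type1	Type3
Hm41	di	Type1	Type3
Hm60	di	Type2	Type3
Hm9	di	Type2	Type3
Hmz9	di	Type2	Type3
Hmz2	di	Type2	Type4
Hm12	di	Type2	Type4
Hm44	di	Type2	Type4
Hm53	di	Type2	Type4
Hm57	di	Type2	Type4
Hm88	di	Type2	Type4
Hm91	di	Type2	Type4
Hmz5	di	Type3	Type4
Hmz1	di	Type3	Type4
Hmz6	di	Type3	Type4
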