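record_no	species	reference	locality	lat	lon	coi_accession
29	Plectostoma christae	BOR 5509	Malaysia, Kelantan, Limestone hill on the right hand side of the road no. 8 direction to Gua Musang, opposite to Quarry Damai	4.896	102.137	KC420288
30	Plectostoma christae	BOR 5505	Malaysia, Kelantan, Bukit Sejuk near Quarry Damai, along the road no. 8 from Gua Musang to Kuala Krai	4.905	102.121	KC420287
31	Plectostoma christae	BOR 5505	Malaysia, Kelantan, Bukit Sejuk near Quarry Damai, along the road no. 8 from Gua Musang to Kuala Krai	4.905	102.121	KC420294
32	Plectostoma christae	BOR 5506	Malaysia, Kelantan, Limestone hills Ciku 2. In the FELDA plantation Ciku 2	4.924	102.177	KC420305
33	Plectostoma christae	BOR 5506	Malaysia, Kelantan, Limestone hills Ciku 2. In the FELDA plantation Ciku 2	4.924	102.177	KC420303
34	Plectostoma christae	BOR 5572	Malaysia, Kelantan, Limestone in FELDA Ciku 5	5.004	102.2	KC420271
35	Plectostoma christae	BOR 5509	Malaysia, Kelantan, Limestone hill on the right hand side of the road no. 8 direction to Gua Musang, opposite to Quarry Damai	4.896	102.137	KC420298
36	Plectostoma christae	BOR 5505	Malaysia, Kelantan, Bukit Sejuk near Quarry Damai, along the road no. 8 from Gua Musang to Kuala Krai	4.905	102.121	KC420269
37	Plectostoma crassipupa	BOR 5512	Malaysia, Kelantan, Limestone hill near Kampung Paloh, on the right hand side of the road no 8 to Gua Musang	4.992	102.228	KC420304
38	Plectostoma crassipupa	BOR 5512	Malaysia, Kelantan, Limestone hill near Kampung Paloh, on the right hand side of the road no 8 to Gua Musang	4.992	102.228	KC420273
39	Plectostoma crassipupa	BOR 5515	Malaysia, Kelantan, Limestone hill in rubber estate (Ulu Kumbang FELCRA)	4.69	101.989	KC420295
40	Plectostoma davisoni	BOR 5508	Malaysia, Kelantan, Limestone hill on the right hand side of the road D29, km 17 from Jelawang to Gua Musang	4.985	101.965	KC250872
41	Plectostoma davisoni	BOR 5508	Malaysia, Kelantan, Limestone hill on the right hand side of the road D29, km 17 from Jelawang to Gua Musang	4.985	101.965	KC420264
42	Plectostoma dindingensis	BOR 5612	Malaysia, Pahang, Dinding	3.846	102.378	KC420285
43	Plectostoma ikanensis	BOR 5504	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC420286
44	Plectostoma ikanensis	BOR 5507	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC420302
45	Plectostoma ikanensis	BOR 5504	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC420301
46	Plectostoma ikanensis	BOR 5504	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC250862
47	Plectostoma ikanensis	BOR 5507	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC420278
48	Plectostoma ikanensis	BOR 5504	Malaysia, Kelantan, Gua Ikan. Loc 1	5.353	102.026	KC420268
49	Plectostoma kakiense	BOR 5516	Malaysia, Perlis, Kaki Bukit	6.645	100.202	KC420265
50	Plectostoma tohchinyawi	BOR 5533	Malaysia, Terengganu, Tasik Kenyir. Gua Bewah	4.851	102.723	KC420289
51	Plectostoma tohchinyawi	BOR 5533	Malaysia, Terengganu, Tasik Kenyir. Gua Bewah	4.851	102.723	KC420307
52	Plectostoma kubuensis	BOR 5519	Malaysia, Perlis, Bukit Kubu. Loc 3	6.404	100.144	KC420272
53	Plectostoma kubuensis	BOR 5519	Malaysia, Perlis, Bukit Kubu. Loc 3	6.404	100.144	KC420270
54	Plectostoma laidlawi	BOR 5510	Malaysia, Kelantan, Limestone hill in Kampung Bayu. About 337 km from Kuala Lumpur by road no. 8	5.09	102.22	KC420279
55	Plectostoma laidlawi	BOR 5510	Malaysia, Kelantan, Limestone hill in Kampung Bayu. About 337 km from Kuala Lumpur by road no. 8	5.09	102.22	KC420300
56	Plectostoma laidlawi	BOR 5571	Malaysia, Kelantan, Limestone in FELDA Ciku 4	5.043	102.196	KC420275
57	Plectostoma mengaburensis	BOR 5574	Malaysia, Pahang, Sri Jaya, Gunung Mengapur	3.731	102.821	KC420299
58	Plectostoma mengaburensis	BOR 5574	Malaysia, Pahang, Sri Jaya, Gunung Mengapur	3.731	102.821	KC420267
59	Plectostoma palinhelix	BOR 5520	Malaysia, Pahang, Bukit Serdam	3.83	101.927	KC250877
60	Plectostoma palinhelix	BOR 5520	Malaysia, Pahang, Bukit Serdam	3.83	101.927	KC420283
61	Plectostoma relauensis	BOR 5511	Malaysia, Kelantan, Taman Negara, Sungai Relau Station. Gua Gajah	4.642	102.063	KC420277
62	Plectostoma retrovertens	BOR 5559	Malaysia, Pahang, Bukit Chintamanis	3.446	102.014	KC420297
63	Plectostoma salpidomon	BOR 5539	Malaysia, Pahang, Kenong Rimba Park. Gunung Kesong	4.194	102.177	KC420276
64	Plectostoma salpidomon	BOR 5542	Malaysia, Pahang, Kenong Rimba Park. Gunung Tangkup	4.194	102.177	KC420296
65	Plectostoma salpidomon	BOR 5541	Malaysia, Pahang, Kenong Rimba Park. Gunung Telahup	4.194	102.177	KC420266
66	Plectostoma salpidomon	BOR 5569	Malaysia, Pahang, Gua Bama	4.194	101.967	KC420280
67	Plectostoma salpidomon	BOR 5569	Malaysia, Pahang, Gua Bama	4.194	101.967	KC250868
68	Plectostoma senex	BOR 5575	Malaysia, Pahang, Gua Charas	3.908	103.147	KC250859
69	Plectostoma sinyumensis	BOR 5537	Malaysia, Pahang, Gunung Jebak Puyuh, near Gunung Senyum	3.7	102.453	KC420291
70	Plectostoma sinyumensis	BOR 5537	Malaysia, Pahang, Gunung Jebak Puyuh, near Gunung Senyum	3.7	102.453	KC250870
71	Plectostoma siphonostomum	BOR 5513	Malaysia, Kelantan, Taman Negara, Sungai Relau Station. Gua Gajah	4.642	102.063	KC420292
72	Plectostoma siphonostomum	BOR 5513	Malaysia, Kelantan, Taman Negara, Sungai Relau Station. Gua Gajah	4.642	102.063	KC420274
73	Plectostoma siphonostomum	BOR 5557	Malaysia, Pahang, Limestone hill on the left hand site of the road no. 8 toward Kuala Lipis. Near Kampung Chegar Perah I and II FELDA	4.487	101.976	KC420306
74	Plectostoma siphonostomum	BOR 5557	Malaysia, Pahang, Limestone hill on the left hand site of the road no. 8 toward Kuala Lipis. Near Kampung Chegar Perah I and II FELDA	4.487	101.976	KC420293
75	Plectostoma siphonostomum	BOR 5557	Malaysia, Pahang, Limestone hill on the left hand site of the road no. 8 toward Kuala Lipis. Near Kampung Chegar Perah I and II FELDA	4.487	101.976	KC250865
76	Plectostoma whitteni	BOR 5536	Malaysia, Terengganu, Tasik Kenyir. Gua Taat	4.842	102.721	KC420284
77	Plectostoma whitteni	BOR 5536	Malaysia, Terengganu, Tasik Kenyir. Gua Taat	4.842	102.721	KC420282
78	Plectostoma umbilicatum	BOR 5503	Malaysia, Pahang, Gua Tongkat	3.891	102.473	KC420281
79	Plectostoma umbilicatum	BOR 5503	Malaysia, Pahang, Gua Tongkat	3.891	102.473	KC420290
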