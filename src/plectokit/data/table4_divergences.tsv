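n_specimens	within	species	christae	crassipupa	davisoni	dindingensis	ikanensis	kakiense	kubuensis	laidlawi	mengaburensis	palinhelix	relauensis	retrovertens	salpidomon	senex	sinyumensis	siphonostomum	tohchinyawi	umbilicatum
8	0.06	Plectostoma christae
3	0.13	Plectostoma crassipupa	0.09
2	0.00	Plectostoma davisoni	0.15	0.12
1	n.a.	Plectostoma dindingensis	0.15	0.14	0.20
6	0.01	Plectostoma ikanensis	0.15	0.11	0.18	0.19
1	n.a.	Plectostoma kakiense	0.14	0.11	0.17	0.21	0.17
2	0.00	Plectostoma kubuensis	0.16	0.14	0.20	0.18	0.19	0.16
3	0.08	Plectostoma laidlawi	0.12	0.09	0.16	0.17	0.16	0.14	0.15
2	0.01	Plectostoma mengaburensis	0.14	0.10	0.18	0.20	0.16	0.16	0.21	0.14
2	0.00	Plectostoma palinhelix	0.13	0.12	0.18	0.15	0.18	0.15	0.20	0.15	0.16
1	n.a.	Plectostoma relauensis	0.12	0.13	0.21	0.17	0.20	0.18	0.19	0.15	0.19	0.14
1	n.a.	Plectostoma retrovertens	0.12	0.13	0.19	0.14	0.18	0.18	0.19	0.17	0.18	0.11	0.15
5	0.04	Plectostoma salpidomon	0.11	0.11	0.15	0.14	0.16	0.16	0.19	0.14	0.15	0.12	0.15	0.12
1	n.a.	Plectostoma senex	0.15	0.14	0.19	0.18	0.19	0.21	0.23	0.15	0.22	0.14	0.19	0.14	0.12
2	0.00	Plectostoma sinyumensis	0.17	0.12	0.19	0.21	0.20	0.18	0.20	0.15	0.19	0.20	0.20	0.20	0.18	0.21
5	0.03	Plectostoma siphonostomum	0.10	0.12	0.17	0.15	0.17	0.17	0.17	0.15	0.17	0.14	0.14	0.12	0.12	0.18	0.19
2	0.00	Plectostoma tohchinyawi	0.13	0.12	0.18	0.16	0.17	0.18	0.20	0.15	0.18	0.12	0.17	0.13	0.16	0.10	0.21	0.14
2	0.00	Plectostoma umbilicatum	0.16	0.13	0.19	0.21	0.19	0.17	0.20	0.16	0.18	0.19	0.20	0.19	0.18	0.22	0.13	0.19	0.20
2	0.01	Plectostoma whitteni	0.15	0.14	0.18	0.16	0.21	0.21	0.23	0.18	0.20	0.15	0.18	0.14	0.11	0.11	0.21	0.15	0.10	0.21
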