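FES	curated human Fe-S cluster binding proteins (editable list)	ABCE1	ACO1	ACO2	BOLA2	BRIP1	CDK5RAP1	CDKAL1	CIAO1	CIAO3	CIAPIN1	CISD1	CISD2	CISD3	DNA2	DPYD	ELP3	ERCC2	FDX1	FDX2	FECH	GLRX3	GLRX5	HSCB	ISCA1	ISCA2	ISCU	LIAS	METTL17	MOCS1	MUTYH	NARF	NDUFS1	NDUFS2	NDUFS7	NDUFS8	NDUFV1	NDUFV2	NFS1	NFU1	NTHL1	NUBP1	NUBP2	POLA1	POLD1	POLE	PPAT	PRIM2	RSAD2	RTEL1	SDHB	TYW1	UQCRFS1	XDH
SSU	mitoribosome small subunit proteins	AURKAIP1	CHCHD1	DAP3	ERAL1	MRPS2	MRPS5	MRPS6	MRPS7	MRPS9	MRPS10	MRPS11	MRPS12	MRPS14	MRPS15	MRPS16	MRPS17	MRPS18A	MRPS18B	MRPS18C	MRPS21	MRPS22	MRPS23	MRPS24	MRPS25	MRPS26	MRPS27	MRPS28	MRPS31	MRPS33	MRPS34	MRPS35	MRPS36	PTCD3
LSU	mitoribosome large subunit proteins	GADD45GIP1	MRPL1	MRPL2	MRPL3	MRPL4	MRPL9	MRPL10	MRPL11	MRPL12	MRPL13	MRPL14	MRPL15	MRPL16	MRPL17	MRPL18	MRPL19	MRPL20	MRPL21	MRPL22	MRPL23	MRPL24	MRPL27	MRPL28	MRPL30	MRPL32	MRPL33	MRPL34	MRPL35	MRPL36	MRPL37	MRPL38	MRPL39	MRPL40	MRPL41	MRPL42	MRPL43	MRPL44	MRPL45	MRPL46	MRPL47	MRPL48	MRPL49	MRPL50	MRPL51	MRPL52	MRPL53	MRPL54	MRPL55	MRPL57
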