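protein	motif	observed	percent_shift	preps_score	svm_call	rrs_ef	ydj1_hm
Ras2	CIIS	+	100	1.281	1	9.011500	4.07
Hmg1	CIKS	-	41	-3.588	0	0.034717	1.93
Rho2	CIIL	+	100	0.817	1	10.313800	3.65
Ssp2	CIDL	-	0	-4.893	0	0.254070	1.82
Skt5, Miy1	CVIM	+	100	2.200	1	3.371400	3.66
Tbs1	CVKM	+	100	-2.909	0	0.066541	2.47
YDL022C-A	CSII	+	100	0.987	1	11.350000	3.34
YBR096W	CSEI	-	0	-5.759	0	0.149720	1.88
YMR265C	CSNA	+	100	-4.848	0	0.039925	3.84
Pet18	CYNA	+	100	-5.843	0	0.079849	4.95
Lih1	CSGL	-	0	-4.577	0	0.041301	2.79
Cup1	CSGK	-	0	-6.461	0	0.099811	1.75
Nap1	CKQS	+	100	-0.975	1	0.066541	4.97
Cst26	CFIF	+	100	-1.924	1	3.194000	4.81
YIL134C-A	CAPY	+	100	-2.164	1	0.199620	4.73
Atr1	CTVA	+	100	0.273	1	7.775800	4.55
Las21	CALD	+	100	-2.887	1	0.028518	4.20
YDL009C	CAVS	+	100	0.237	1	6.607500	4.69
Sua5	CIQF	+	100	-0.601	1	0.199620	5.49
NA	CAAQ	+	100	-3.280	1	0.399250	4.82
NA	CAHQ	+	100	-3.599	1	0.399250	4.74
NA	CASA	+	100	-2.693	1	0.243980	3.91
NA	CKQH	+	70	-2.442	1	0.399250	4.37
NA	CNLI	+	95	-3.804	1	0.133080	3.84
NA	CSFL	+	68	-4.425	1	0.108890	4.28
NA	CVAA	+	100	-2.789	1	0.079849	4.81
NA	CVFM	+	100	-2.939	1	2.395500	4.76
NA	CKQG	+	73	-1.876	0	0.099811	4.06
NA	CKQL	+	50	-1.680	0	0.057035	3.84
NA	CQTS	+	100	-0.922	0	0.057035	5.44
NA	CQSQ	+	100	-1.624	1	0.159700	5.27
NA	CKQA	+	95	-1.149	1	0.133080	4.57
NA	CKQC	+	100	-0.745	1	0.099811	4.12
NA	CKQD	+	67	-4.103	0	0.066541	3.51
NA	CKQE	-	19	-3.745	0	0.066541	3.36
NA	CKQF	-	28	-2.345	0	0.057035	4.62
NA	CKQH	+	73	-2.442	1	0.399250	4.37
NA	CKQI	+	70	-1.700	1	0.099811	3.90
NA	CKQK	-	0	-4.010	0	0.036295	2.22
NA	CKQM	+	100	-1.045	1	0.133080	4.50
NA	CKQN	+	88	-5.046	0	0.199620	4.48
NA	CKQP	-	13	-2.887	0	0.399250	1.97
NA	CKQQ	+	100	-0.747	1	0.399250	5.35
NA	CKQR	-	0	-4.533	0	0.399250	1.77
NA	CKQT	+	96	-1.874	1	0.079849	4.68
NA	CKQV	+	100	-1.744	1	0.133080	4.50
NA	CKQW	+	71	-5.184	0	0.199620	3.57
NA	CKQY	+	100	-3.326	0	0.399250	4.50
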