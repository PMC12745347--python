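population	latitude	longitude	sampling_year	n	private_alleles	ho	he	pi	pop_fst
a'Bhaid-Luachraich	57.81	-5.55	2012	10	32	0.093	0.075	0.080	0.512
a'Garbh-bhaid Mor	58.39	-4.95	2021	10	80	0.065	0.048	0.051	0.688
Ard Achadh	55.36	-6.16	2021	10	164	0.048	0.039	0.042	0.741
Arkaig (Benthivore)	56.97	-5.14	2007	4	0	0.116	0.094	0.110	0.329
Arkaig (Planktivore)	56.97	-5.14	2007	5	0	0.116	0.098	0.110	0.327
Awe (Benthivore)	56.30	-5.23	1997	5	0	0.119	0.108	0.125	0.245
Awe (Planktivore)	56.30	-5.23	1997	5	0	0.121	0.103	0.119	0.279
Bodlyn	52.80	-4.01	2002	2	0	0.112	0.089	0.128	0.210
Braig horrisdale	57.67	-5.67	2016	9	75	0.067	0.056	0.060	0.633
Brora	58.05	-3.95	2010	4	1	0.095	0.074	0.088	0.461
Bruicheach	57.39	-4.58	2009	8	24	0.075	0.059	0.065	0.601
Bunaveela	54.02	-9.54	2001	10	127	0.054	0.044	0.047	0.714
Calder	58.52	-3.59	2021	3	0	0.108	0.084	0.102	0.377
Conniston	54.34	-3.07	2005	1	0	0.129	0.065	0.129	0.165
Coulin	57.55	-5.35	1997	9	0	0.079	0.066	0.071	0.566
Damh	57.50	-5.57	2008	2	0	0.112	0.069	0.104	0.355
Doine	56.34	-4.48	1997	4	0	0.118	0.088	0.106	0.353
Doon	55.24	-4.37	1997	6	0	0.112	0.090	0.100	0.387
Dubh	56.88	-5.71	2021	5	12	0.124	0.091	0.108	0.339
Dughaill (Benthivore)	57.47	-5.35	2013	5	2	0.102	0.087	0.098	0.401
Dughaill (Planktivore)	57.47	-5.35	2013	5	0	0.105	0.093	0.105	0.361
Duntelchaig	57.35	-4.29	2010	4	0	0.122	0.089	0.113	0.305
Earn	56.38	-4.23	2016	9	27	0.102	0.083	0.089	0.453
Eck	56.08	-4.99	1997	10	59	0.060	0.049	0.057	0.653
Ericht (Benthivore)	56.82	-4.39	2007	4	1	0.127	0.106	0.126	0.229
Ericht (Planktivore)	56.82	-4.39	2007	5	0	0.145	0.121	0.136	0.166
Fannich	57.64	-4.96	2007	9	2	0.068	0.056	0.060	0.634
Finn	54.86	-8.14	2012	1	0	0.051	0.025	0.051	0.679
Garry	56.80	-4.25	2007	8	2	0.115	0.095	0.103	0.373
Insh	57.12	-3.93	2007	10	8	0.092	0.077	0.082	0.498
Kindrum	55.23	-7.71	1997	7	43	0.072	0.058	0.065	0.605
Laggan	56.92	-4.55	2007	6	0	0.115	0.099	0.110	0.328
Langavat	58.04	-6.82	1997	10	81	0.087	0.074	0.078	0.522
Lee	56.90	-2.95	1997	9	35	0.108	0.090	0.096	0.413
Loch	56.85	-3.67	2007	10	83	0.037	0.029	0.031	0.808
Lochy (Benthivore)	56.96	-4.92	2009	2	0	0.188	0.124	0.171	-0.045
Lochy (Planktivore)	56.96	-4.92	2009	5	0	0.123	0.104	0.116	0.288
Lubnaig	56.30	-4.30	1997	10	2	0.103	0.078	0.100	0.387
Luichart	57.62	-4.78	2009	10	29	0.102	0.086	0.092	0.440
Maree	57.71	-5.53	2008	10	7	0.131	0.117	0.124	0.243
Meadie	58.33	-4.56	2007	5	2	0.101	0.078	0.089	0.457
Mealt	57.61	-6.18	2009	2	0	0.029	0.018	0.027	0.837
Merkland	58.23	-4.73	1997	10	26	0.068	0.052	0.065	0.601
More	58.28	-4.87	1998	4	0	0.121	0.091	0.113	0.309
Morie	57.75	-4.47	2009	3	0	0.123	0.087	0.116	0.279
Nam Brac	58.38	-5.12	2010	3	0	0.085	0.062	0.081	0.503
naSealga (Benthivore)	57.79	-5.31	2015	5	0	0.089	0.071	0.083	0.497
naSealga (Planktivore)	57.79	-5.31	2015	5	0	0.088	0.072	0.084	0.492
Naver	58.30	-4.35	2011	9	27	0.118	0.100	0.107	0.346
Osgaig	58.05	-5.32	2015	9	35	0.086	0.073	0.079	0.517
Padarn	53.13	-4.13	2020	10	65	0.095	0.082	0.087	0.469
Rannoch (Benthivore)	56.70	-4.23	2010	1	0	0.101	0.050	0.101	0.382
Rannoch (Planktivore)	56.70	-4.23	2010	6	5	0.115	0.098	0.109	0.215
Rannoch (Piscivore)	56.70	-4.23	2010	4	0	0.133	0.111	0.128	0.336
Seil	56.32	-5.55	2021	9	77	0.046	0.039	0.042	0.746
Shin	58.12	-4.57	1997	7	1	0.111	0.095	0.104	0.364
Stack	58.34	-4.92	1997	5	0	0.115	0.102	0.118	0.279
Talla	55.48	-3.40	1997	8	0	0.098	0.084	0.091	0.444
Tarff	57.15	-4.61	2012	8	57	0.049	0.038	0.042	0.744
Tay (Benthivore)	56.52	-4.14	1997	5	1	0.127	0.105	0.122	0.257
Tay (Planktivore)	56.52	-4.14	1997	5	1	0.121	0.107	0.123	0.254
Treig	56.81	-4.73	2007	7	0	0.127	0.124	0.135	0.174
Tummel	56.71	-3.95	2007	9	18	0.126	0.105	0.113	0.308
Uaine	57.52	-5.39	1997	10	0	0.067	0.060	0.064	0.611
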