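gene_id	role	alpha_sex	beta_cal	gamma_int	chromosome
g00000	sex	1.5	0	0	1
g00001	sex	1.5	0	0	18
g00002	sex	1.5	0	0	6
g00003	sex	1.5	0	0	16
g00004	sex	1.5	0	0	13
g00005	sex	1.5	0	0	17
g00006	sex	1.5	0	0	10
g00007	sex	1.5	0	0	15
g00008	sex	1.5	0	0	19
g00009	sex	1.5	0	0	13
g00010	calcification	0	2	0	14
g00011	calcification	0	2	0	18
g00012	calcification	0	2	0	16
g00013	calcification	0	2	0	3
g00014	calcification	0	2	0	8
g00015	calcification	0	2	0	6
g00016	calcification	0	2	0	4
g00017	calcification	0	2	0	18
g00018	calcification	0	2	0	18
g00019	calcification	0	2	0	11
g00020	interaction	0	2	2	10
g00021	interaction	0	2	2	6
g00022	interaction	0	2	2	22
g00023	interaction	0	2	2	10
g00024	interaction	0	2	2	18
g00025	interaction	0	2	2	17
g00026	interaction	0	2	2	1
g00027	interaction	0	2	2	20
g00028	interaction	0	2	2	11
g00029	interaction	0	2	2	14
g00030	chrX_escape	-1.5	0	0	X
g00031	chrX_escape	-1.5	0	0	X
g00032	chrX_escape	-1.5	0	0	X
g00033	chrX_escape	-1.5	0	0	X
g00034	chrX_escape	-1.5	0	0	X
g00035	chrY	1.5	0	0	Y
g00036	chrY	1.5	0	0	Y
g00037	chrY	1.5	0	0	Y
g00038	chrY	1.5	0	0	Y
g00039	chrY	1.5	0	0	Y
g00040	null	0	0	0	21
g00041	null	0	0	0	14
g00042	null	0	0	0	6
g00043	null	0	0	0	12
g00044	null	0	0	0	10
g00045	null	0	0	0	2
g00046	null	0	0	0	10
g00047	null	0	0	0	11
g00048	null	0	0	0	22
g00049	null	0	0	0	4
g00050	null	0	0	0	7
g00051	null	0	0	0	9
g00052	null	0	0	0	19
g00053	null	0	0	0	18
g00054	null	0	0	0	12
g00055	null	0	0	0	21
g00056	null	0	0	0	14
g00057	null	0	0	0	21
g00058	null	0	0	0	12
g00059	null	0	0	0	7
g00060	null	0	0	0	20
g00061	null	0	0	0	10
g00062	null	0	0	0	7
g00063	null	0	0	0	2
g00064	null	0	0	0	4
g00065	null	0	0	0	12
g00066	null	0	0	0	10
g00067	null	0	0	0	21
g00068	null	0	0	0	18
g00069	null	0	0	0	19
g00070	null	0	0	0	19
g00071	null	0	0	0	22
g00072	null	0	0	0	13
g00073	null	0	0	0	13
g00074	null	0	0	0	17
g00075	null	0	0	0	6
g00076	null	0	0	0	18
g00077	null	0	0	0	10
g00078	null	0	0	0	7
g00079	null	0	0	0	12
g00080	null	0	0	0	5
g00081	null	0	0	0	4
g00082	null	0	0	0	19
g00083	null	0	0	0	12
g00084	null	0	0	0	5
g00085	null	0	0	0	12
g00086	null	0	0	0	17
g00087	null	0	0	0	6
g00088	null	0	0	0	7
g00089	null	0	0	0	2
g00090	null	0	0	0	4
g00091	null	0	0	0	8
g00092	null	0	0	0	3
g00093	null	0	0	0	6
g00094	null	0	0	0	16
g00095	null	0	0	0	10
g00096	null	0	0	0	4
g00097	null	0	0	0	21
g00098	null	0	0	0	3
g00099	null	0	0	0	21
g00100	null	0	0	0	20
g00101	null	0	0	0	22
g00102	null	0	0	0	3
g00103	null	0	0	0	15
g00104	null	0	0	0	12
g00105	null	0	0	0	13
g00106	null	0	0	0	6
g00107	null	0	0	0	7
g00108	null	0	0	0	5
g00109	null	0	0	0	16
g00110	null	0	0	0	19
g00111	null	0	0	0	4
g00112	null	0	0	0	20
g00113	null	0	0	0	21
g00114	null	0	0	0	6
g00115	null	0	0	0	18
g00116	null	0	0	0	10
g00117	null	0	0	0	9
g00118	null	0	0	0	11
g00119	null	0	0	0	18
g00120	null	0	0	0	3
g00121	null	0	0	0	12
g00122	null	0	0	0	13
g00123	null	0	0	0	4
g00124	null	0	0	0	14
g00125	null	0	0	0	9
g00126	null	0	0	0	9
g00127	null	0	0	0	8
g00128	null	0	0	0	9
g00129	null	0	0	0	10
g00130	null	0	0	0	7
g00131	null	0	0	0	10
g00132	null	0	0	0	9
g00133	null	0	0	0	9
g00134	null	0	0	0	6
g00135	null	0	0	0	10
g00136	null	0	0	0	17
g00137	null	0	0	0	12
g00138	null	0	0	0	7
g00139	null	0	0	0	4
g00140	null	0	0	0	21
g00141	null	0	0	0	1
g00142	null	0	0	0	5
g00143	null	0	0	0	3
g00144	null	0	0	0	21
g00145	null	0	0	0	22
g00146	null	0	0	0	8
g00147	null	0	0	0	21
g00148	null	0	0	0	13
g00149	null	0	0	0	10
g00150	null	0	0	0	19
g00151	null	0	0	0	17
g00152	null	0	0	0	3
g00153	null	0	0	0	1
g00154	null	0	0	0	8
g00155	null	0	0	0	8
g00156	null	0	0	0	8
g00157	null	0	0	0	12
g00158	null	0	0	0	4
g00159	null	0	0	0	1
g00160	null	0	0	0	11
g00161	null	0	0	0	12
g00162	null	0	0	0	20
g00163	null	0	0	0	13
g00164	null	0	0	0	11
g00165	null	0	0	0	2
g00166	null	0	0	0	20
g00167	null	0	0	0	10
g00168	null	0	0	0	5
g00169	null	0	0	0	12
g00170	null	0	0	0	7
g00171	null	0	0	0	9
g00172	null	0	0	0	19
g00173	null	0	0	0	3
g00174	null	0	0	0	19
g00175	null	0	0	0	2
g00176	null	0	0	0	22
g00177	null	0	0	0	19
g00178	null	0	0	0	12
g00179	null	0	0	0	16
g00180	null	0	0	0	6
g00181	null	0	0	0	11
g00182	null	0	0	0	3
g00183	null	0	0	0	8
g00184	null	0	0	0	13
g00185	null	0	0	0	17
g00186	null	0	0	0	12
g00187	null	0	0	0	7
g00188	null	0	0	0	17
g00189	null	0	0	0	15
g00190	null	0	0	0	15
g00191	null	0	0	0	7
g00192	null	0	0	0	7
g00193	null	0	0	0	6
g00194	null	0	0	0	14
g00195	null	0	0	0	14
g00196	null	0	0	0	16
g00197	null	0	0	0	12
g00198	null	0	0	0	21
g00199	null	0	0	0	12
g00200	null	0	0	0	7
g00201	null	0	0	0	13
g00202	null	0	0	0	13
g00203	null	0	0	0	2
g00204	null	0	0	0	6
g00205	null	0	0	0	8
g00206	null	0	0	0	4
g00207	null	0	0	0	9
g00208	null	0	0	0	2
g00209	null	0	0	0	16
g00210	null	0	0	0	20
g00211	null	0	0	0	13
g00212	null	0	0	0	15
g00213	null	0	0	0	1
g00214	null	0	0	0	7
g00215	null	0	0	0	8
g00216	null	0	0	0	21
g00217	null	0	0	0	22
g00218	null	0	0	0	19
g00219	null	0	0	0	1
g00220	null	0	0	0	13
g00221	null	0	0	0	18
g00222	null	0	0	0	10
g00223	null	0	0	0	8
g00224	null	0	0	0	22
g00225	null	0	0	0	5
g00226	null	0	0	0	13
g00227	null	0	0	0	8
g00228	null	0	0	0	6
g00229	null	0	0	0	1
g00230	null	0	0	0	3
g00231	null	0	0	0	10
g00232	null	0	0	0	14
g00233	null	0	0	0	12
g00234	null	0	0	0	8
g00235	null	0	0	0	13
g00236	null	0	0	0	10
g00237	null	0	0	0	5
g00238	null	0	0	0	20
g00239	null	0	0	0	10
g00240	null	0	0	0	5
g00241	null	0	0	0	5
g00242	null	0	0	0	17
g00243	null	0	0	0	12
g00244	null	0	0	0	7
g00245	null	0	0	0	16
g00246	null	0	0	0	7
g00247	null	0	0	0	6
g00248	null	0	0	0	20
g00249	null	0	0	0	10
g00250	null	0	0	0	5
g00251	null	0	0	0	15
g00252	null	0	0	0	20
g00253	null	0	0	0	16
g00254	null	0	0	0	21
g00255	null	0	0	0	2
g00256	null	0	0	0	6
g00257	null	0	0	0	12
g00258	null	0	0	0	6
g00259	null	0	0	0	21
g00260	null	0	0	0	14
g00261	null	0	0	0	4
g00262	null	0	0	0	13
g00263	null	0	0	0	21
g00264	null	0	0	0	14
g00265	null	0	0	0	8
g00266	null	0	0	0	3
g00267	null	0	0	0	7
g00268	null	0	0	0	5
g00269	null	0	0	0	7
g00270	null	0	0	0	4
g00271	null	0	0	0	19
g00272	null	0	0	0	12
g00273	null	0	0	0	5
g00274	null	0	0	0	3
g00275	null	0	0	0	19
g00276	null	0	0	0	3
g00277	null	0	0	0	9
g00278	null	0	0	0	11
g00279	null	0	0	0	22
g00280	null	0	0	0	21
g00281	null	0	0	0	15
g00282	null	0	0	0	15
g00283	null	0	0	0	4
g00284	null	0	0	0	11
g00285	null	0	0	0	11
g00286	null	0	0	0	12
g00287	null	0	0	0	16
g00288	null	0	0	0	19
g00289	null	0	0	0	16
g00290	null	0	0	0	22
g00291	null	0	0	0	13
g00292	null	0	0	0	6
g00293	null	0	0	0	2
g00294	null	0	0	0	10
g00295	null	0	0	0	5
g00296	null	0	0	0	20
g00297	null	0	0	0	19
g00298	null	0	0	0	12
g00299	null	0	0	0	17
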