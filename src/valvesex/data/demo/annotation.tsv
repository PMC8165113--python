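gene_id	symbol	chromosome
g00000	G00000	1
g00001	G00001	18
g00002	G00002	6
g00003	G00003	16
g00004	G00004	13
g00005	G00005	17
g00006	G00006	10
g00007	G00007	15
g00008	G00008	19
g00009	G00009	13
g00010	G00010	14
g00011	G00011	18
g00012	G00012	16
g00013	G00013	3
g00014	G00014	8
g00015	G00015	6
g00016	G00016	4
g00017	G00017	18
g00018	G00018	18
g00019	G00019	11
g00020	G00020	10
g00021	G00021	6
g00022	G00022	22
g00023	G00023	10
g00024	G00024	18
g00025	G00025	17
g00026	G00026	1
g00027	G00027	20
g00028	G00028	11
g00029	G00029	14
g00030	G00030	X
g00031	G00031	X
g00032	G00032	X
g00033	G00033	X
g00034	G00034	X
g00035	G00035	Y
g00036	G00036	Y
g00037	G00037	Y
g00038	G00038	Y
g00039	G00039	Y
g00040	G00040	21
g00041	G00041	14
g00042	G00042	6
g00043	G00043	12
g00044	G00044	10
g00045	G00045	2
g00046	G00046	10
g00047	G00047	11
g00048	G00048	22
g00049	G00049	4
g00050	G00050	7
g00051	G00051	9
g00052	G00052	19
g00053	G00053	18
g00054	G00054	12
g00055	G00055	21
g00056	G00056	14
g00057	G00057	21
g00058	G00058	12
g00059	G00059	7
g00060	G00060	20
g00061	G00061	10
g00062	G00062	7
g00063	G00063	2
g00064	G00064	4
g00065	G00065	12
g00066	G00066	10
g00067	G00067	21
g00068	G00068	18
g00069	G00069	19
g00070	G00070	19
g00071	G00071	22
g00072	G00072	13
g00073	G00073	13
g00074	G00074	17
g00075	G00075	6
g00076	G00076	18
g00077	G00077	10
g00078	G00078	7
g00079	G00079	12
g00080	G00080	5
g00081	G00081	4
g00082	G00082	19
g00083	G00083	12
g00084	G00084	5
g00085	G00085	12
g00086	G00086	17
g00087	G00087	6
g00088	G00088	7
g00089	G00089	2
g00090	G00090	4
g00091	G00091	8
g00092	G00092	3
g00093	G00093	6
g00094	G00094	16
g00095	G00095	10
g00096	G00096	4
g00097	G00097	21
g00098	G00098	3
g00099	G00099	21
g00100	G00100	20
g00101	G00101	22
g00102	G00102	3
g00103	G00103	15
g00104	G00104	12
g00105	G00105	13
g00106	G00106	6
g00107	G00107	7
g00108	G00108	5
g00109	G00109	16
g00110	G00110	19
g00111	G00111	4
g00112	G00112	20
g00113	G00113	21
g00114	G00114	6
g00115	G00115	18
g00116	G00116	10
g00117	G00117	9
g00118	G00118	11
g00119	G00119	18
g00120	G00120	3
g00121	G00121	12
g00122	G00122	13
g00123	G00123	4
g00124	G00124	14
g00125	G00125	9
g00126	G00126	9
g00127	G00127	8
g00128	G00128	9
g00129	G00129	10
g00130	G00130	7
g00131	G00131	10
g00132	G00132	9
g00133	G00133	9
g00134	G00134	6
g00135	G00135	10
g00136	G00136	17
g00137	G00137	12
g00138	G00138	7
g00139	G00139	4
g00140	G00140	21
g00141	G00141	1
g00142	G00142	5
g00143	G00143	3
g00144	G00144	21
g00145	G00145	22
g00146	G00146	8
g00147	G00147	21
g00148	G00148	13
g00149	G00149	10
g00150	G00150	19
g00151	G00151	17
g00152	G00152	3
g00153	G00153	1
g00154	G00154	8
g00155	G00155	8
g00156	G00156	8
g00157	G00157	12
g00158	G00158	4
g00159	G00159	1
g00160	G00160	11
g00161	G00161	12
g00162	G00162	20
g00163	G00163	13
g00164	G00164	11
g00165	G00165	2
g00166	G00166	20
g00167	G00167	10
g00168	G00168	5
g00169	G00169	12
g00170	G00170	7
g00171	G00171	9
g00172	G00172	19
g00173	G00173	3
g00174	G00174	19
g00175	G00175	2
g00176	G00176	22
g00177	G00177	19
g00178	G00178	12
g00179	G00179	16
g00180	G00180	6
g00181	G00181	11
g00182	G00182	3
g00183	G00183	8
g00184	G00184	13
g00185	G00185	17
g00186	G00186	12
g00187	G00187	7
g00188	G00188	17
g00189	G00189	15
g00190	G00190	15
g00191	G00191	7
g00192	G00192	7
g00193	G00193	6
g00194	G00194	14
g00195	G00195	14
g00196	G00196	16
g00197	G00197	12
g00198	G00198	21
g00199	G00199	12
g00200	G00200	7
g00201	G00201	13
g00202	G00202	13
g00203	G00203	2
g00204	G00204	6
g00205	G00205	8
g00206	G00206	4
g00207	G00207	9
g00208	G00208	2
g00209	G00209	16
g00210	G00210	20
g00211	G00211	13
g00212	G00212	15
g00213	G00213	1
g00214	G00214	7
g00215	G00215	8
g00216	G00216	21
g00217	G00217	22
g00218	G00218	19
g00219	G00219	1
g00220	G00220	13
g00221	G00221	18
g00222	G00222	10
g00223	G00223	8
g00224	G00224	22
g00225	G00225	5
g00226	G00226	13
g00227	G00227	8
g00228	G00228	6
g00229	G00229	1
g00230	G00230	3
g00231	G00231	10
g00232	G00232	14
g00233	G00233	12
g00234	G00234	8
g00235	G00235	13
g00236	G00236	10
g00237	G00237	5
g00238	G00238	20
g00239	G00239	10
g00240	G00240	5
g00241	G00241	5
g00242	G00242	17
g00243	G00243	12
g00244	G00244	7
g00245	G00245	16
g00246	G00246	7
g00247	G00247	6
g00248	G00248	20
g00249	G00249	10
g00250	G00250	5
g00251	G00251	15
g00252	G00252	20
g00253	G00253	16
g00254	G00254	21
g00255	G00255	2
g00256	G00256	6
g00257	G00257	12
g00258	G00258	6
g00259	G00259	21
g00260	G00260	14
g00261	G00261	4
g00262	G00262	13
g00263	G00263	21
g00264	G00264	14
g00265	G00265	8
g00266	G00266	3
g00267	G00267	7
g00268	G00268	5
g00269	G00269	7
g00270	G00270	4
g00271	G00271	19
g00272	G00272	12
g00273	G00273	5
g00274	G00274	3
g00275	G00275	19
g00276	G00276	3
g00277	G00277	9
g00278	G00278	11
g00279	G00279	22
g00280	G00280	21
g00281	G00281	15
g00282	G00282	15
g00283	G00283	4
g00284	G00284	11
g00285	G00285	11
g00286	G00286	12
g00287	G00287	16
g00288	G00288	19
g00289	G00289	16
g00290	G00290	22
g00291	G00291	13
g00292	G00292	6
g00293	G00293	2
g00294	G00294	10
g00295	G00295	5
g00296	G00296	20
g00297	G00297	19
g00298	G00298	12
g00299	G00299	17
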