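sample_id	patient_id	sex	tissue
M001_nondiseased	M001	M	nondiseased
M001_intermediate	M001	M	intermediate
M001_calcified	M001	M	calcified
M002_nondiseased	M002	M	nondiseased
M002_intermediate	M002	M	intermediate
M002_calcified	M002	M	calcified
M003_nondiseased	M003	M	nondiseased
M003_intermediate	M003	M	intermediate
M003_calcified	M003	M	calcified
M004_nondiseased	M004	M	nondiseased
M004_intermediate	M004	M	intermediate
M004_calcified	M004	M	calcified
M005_nondiseased	M005	M	nondiseased
M005_intermediate	M005	M	intermediate
M005_calcified	M005	M	calcified
M006_nondiseased	M006	M	nondiseased
M006_intermediate	M006	M	intermediate
M006_calcified	M006	M	calcified
M007_nondiseased	M007	M	nondiseased
M007_intermediate	M007	M	intermediate
M007_calcified	M007	M	calcified
M008_nondiseased	M008	M	nondiseased
M008_intermediate	M008	M	intermediate
M008_calcified	M008	M	calcified
M009_nondiseased	M009	M	nondiseased
M009_intermediate	M009	M	intermediate
M009_calcified	M009	M	calcified
M010_nondiseased	M010	M	nondiseased
M010_intermediate	M010	M	intermediate
M010_calcified	M010	M	calcified
M011_nondiseased	M011	M	nondiseased
M011_intermediate	M011	M	intermediate
M011_calcified	M011	M	calcified
M012_nondiseased	M012	M	nondiseased
M012_intermediate	M012	M	intermediate
M012_calcified	M012	M	calcified
F001_nondiseased	F001	F	nondiseased
F001_intermediate	F001	F	intermediate
F001_calcified	F001	F	calcified
F002_nondiseased	F002	F	nondiseased
F002_intermediate	F002	F	intermediate
F002_calcified	F002	F	calcified
F003_nondiseased	F003	F	nondiseased
F003_intermediate	F003	F	intermediate
F003_calcified	F003	F	calcified
F004_nondiseased	F004	F	nondiseased
F004_intermediate	F004	F	intermediate
F004_calcified	F004	F	calcified
F005_nondiseased	F005	F	nondiseased
F005_intermediate	F005	F	intermediate
F005_calcified	F005	F	calcified
F006_nondiseased	F006	F	nondiseased
F006_intermediate	F006	F	intermediate
F006_calcified	F006	F	calcified
F007_nondiseased	F007	F	nondiseased
F007_intermediate	F007	F	intermediate
F007_calcified	F007	F	calcified
F008_nondiseased	F008	F	nondiseased
F008_intermediate	F008	F	intermediate
F008_calcified	F008	F	calcified
F009_nondiseased	F009	F	nondiseased
F009_intermediate	F009	F	intermediate
F009_calcified	F009	F	calcified
F010_nondiseased	F010	F	nondiseased
F010_intermediate	F010	F	intermediate
F010_calcified	F010	F	calcified
F011_nondiseased	F011	F	nondiseased
F011_intermediate	F011	F	intermediate
F011_calcified	F011	F	calcified
F012_nondiseased	F012	F	nondiseased
F012_intermediate	F012	F	intermediate
F012_calcified	F012	F	calcified
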