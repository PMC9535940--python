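nt_pos	ref	alt	protein_change	count_actA	cov_actA	count_actB	cov_actB	count_lof	cov_lof
1325	G	T	S442I	2500	100000	1800	100000	20	100000
1973	T	A	L658Q	1500	100000	900	100000	10	100000
2303	G	T	S768I	4000	100000	3500	100000	30	100000
2369	C	T	T790M	2200	100000	500	100000	25	100000
2573	T	G	L858R	9000	100000	8000	100000	100	100000
2781	G	A	L927L	1200	100000	1100	100000	50	100000
3385	C	T	H1129Y	1300	100000	200	100000	15	100000
866	C	T	A289V	900	100000	800	100000	10	100000
2155	G	A	G719S	2000	100000	1900	100000	1800	100000
2330	T	C	L777P	3000	100000	2800	100000	100	100000
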