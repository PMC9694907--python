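outcome	analysis	source	n_case	n_control	beta	se	or_printed	ci_low_printed	ci_high_printed
Cataract	phewas_bmi_adjusted	UK-Biobank-like PheWAS	33716	304456	-0.120	0.029	0.89	0.84	0.94
Macular degeneration (senile) of retina	phewas_bmi_adjusted	UK-Biobank-like PheWAS	5276	321852	-0.231	0.067	0.79	0.70	0.91
Anal and rectal polyp	phewas_bmi_adjusted	UK-Biobank-like PheWAS	10117	309827	-0.161	0.050	0.85	0.77	0.94
Hypercholesterolemia	phewas_bmi_adjusted	UK-Biobank-like PheWAS	43956	290520	-0.094	0.026	0.91	0.86	0.96
Type 2 diabetes	two_sample_bmi_adjusted	DIAGRAM (BMI adjustment)	74124	824006	-0.088	0.029	0.92	0.86	0.97
Type 2 diabetes	two_sample	DIAGRAM (no BMI adjustment)	74124	824006	-0.029	0.029	0.97	0.92	1.03
Type 2 diabetes	two_sample	FinnGen	41245	215160	0.029	0.029	1.03	0.97	1.09
Type 1 diabetes	two_sample	type 1 diabetes GWAS	18942	501638	-0.058	0.058	0.94	0.84	1.06
Cataract	two_sample	FinnGen	32692	224812	-0.088	0.029	0.92	0.86	0.97
Benign neoplasm of ascending colon	two_sample	FinnGen	1605	208187	-0.146	0.117	0.86	0.69	1.09
Benign neoplasm of transverse colon	two_sample	FinnGen	1261	208341	-0.292	0.117	0.75	0.59	0.94
Benign neoplasm of sigmoid colon	two_sample	FinnGen	2695	257710	-0.146	0.088	0.86	0.73	1.03
Benign neoplasm of colon	two_sample	FinnGen	9208	203426	-0.088	0.058	0.92	0.82	1.03
Benign neoplasm of colon, rectum, anus, and anal canal	two_sample	FinnGen	11490	202006	-0.058	0.029	0.94	0.89	1.00
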