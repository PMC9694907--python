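icd_code,vocabulary,phecode,label,category,exclude_low,exclude_high,sex
E13.9,ICD10,250,Diabetes mellitus,endocrine/metabolic,249,250.99,
E14.9,ICD10,250,Diabetes mellitus,endocrine/metabolic,249,250.99,
2509,ICD9,250,Diabetes mellitus,endocrine/metabolic,249,250.99,
E11.9,ICD10,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,
E11.8,ICD10,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,
25000,ICD9,250.2,Type 2 diabetes,endocrine/metabolic,249,250.99,
E78.9,ICD10,272,Disorders of lipoid metabolism,endocrine/metabolic,270,272.99,
E78.5,ICD10,272,Disorders of lipoid metabolism,endocrine/metabolic,270,272.99,
2724,ICD9,272,Disorders of lipoid metabolism,endocrine/metabolic,270,272.99,
E78.1,ICD10,272.1,Hyperlipidemia,endocrine/metabolic,270,272.99,
E78.2,ICD10,272.1,Hyperlipidemia,endocrine/metabolic,270,272.99,
2721,ICD9,272.1,Hyperlipidemia,endocrine/metabolic,270,272.99,
E78.0,ICD10,272.11,Hypercholesterolemia,endocrine/metabolic,270,272.99,
E78.00,ICD10,272.11,Hypercholesterolemia,endocrine/metabolic,270,272.99,
2720,ICD9,272.11,Hypercholesterolemia,endocrine/metabolic,270,272.99,
H35.30,ICD10,362.29,Macular degeneration (senile) of retina,sense organs,362,362.99,
H35.31,ICD10,362.29,Macular degeneration (senile) of retina,sense organs,362,362.99,
36250,ICD9,362.29,Macular degeneration (senile) of retina,sense organs,362,362.99,
H25.1,ICD10,366,Cataract,sense organs,,,
H26.9,ICD10,366,Cataract,sense organs,,,
3669,ICD9,366,Cataract,sense organs,,,
I10,ICD10,401,Hypertension,circulatory system,401,405.99,
I15.9,ICD10,401,Hypertension,circulatory system,401,405.99,
4019,ICD9,401,Hypertension,circulatory system,401,405.99,
J45.9,ICD10,495,Asthma,respiratory,,,
J45.0,ICD10,495,Asthma,respiratory,,,
49390,ICD9,495,Asthma,respiratory,,,
K62.0,ICD10,565.1,Anal and rectal polyp,digestive,,,
K62.1,ICD10,565.1,Anal and rectal polyp,digestive,,,
5690,ICD9,565.1,Anal and rectal polyp,digestive,,,
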