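subject_id,age,sex,consanguinity,family_history,n_affected_family,tumour_size_cm,lymph_node,grade,position,estrogen_receptor,progesterone,brca1,brca2,other_genes,diagnosis,classification,class_label,reported_fuzzy_score,reported_network_score
S01,43,Female,Unknown,Unknown,Unknown,17.5,Negative,Unknown,Right Breast,Unknown,Positive,Negative,Positive,Negative,Yes,Pathogenic,Pathogenic,0.900,0.999
S02,36,Female,Unknown,Unknown,Unknown,0.5,Negative,Grade 2,Right Breast,Unknown,Positive,Negative,Positive,Negative,Yes,Pathogenic,Pathogenic,0.890,0.999
S03,44,Female,Yes,Yes,1,Unknown,Unknown,Unknown,Right Breast,Unknown,Unknown,Positive,Negative,Negative,Yes,Pathogenic,Pathogenic,0.900,0.999
S04,42,Female,Unknown,Unknown,Unknown,6.6,Negative,Grade 3,Right Breast,Positive,Negative,Positive,Negative,Negative,Yes,Pathogenic,Pathogenic,0.900,0.999
S05,34,Female,Yes,Yes,1,Unknown,Unknown,Unknown,Right Breast,Unknown,Unknown,Positive,Negative,Negative,Unknown,Likely Pathogenic,Likely Pathogenic,0.661,0.778
S06,33,Female,Unknown,Yes,3,Unknown,Unknown,Unknown,Unknown,Unknown,Unknown,Positive,Negative,Negative,No,Likely Pathogenic,Likely Pathogenic,0.661,0.751
S07,38,Female,Unknown,No,0,3.5,Negative,Grade 3,Right Breast,Positive,Positive,Positive,Positive,Negative,Yes,VUS,VUS,0.425,0.502
S08,42,Female,No,No,0,0.5,Negative,Grade 2,Right Breast,Positive,Positive,Negative,Positive,Negative,Yes,VUS,VUS,0.489,0.499
S09,58,Female,Unknown,Yes,Unknown,Unknown,Unknown,Grade 2,Right Breast,Positive,Positive,Positive,Negative,Negative,Yes,VUS,VUS,0.489,0.505
S10,58,Female,Unknown,No,0,Unknown,Positive,Grade 2,Right Breast,Positive,Positive,Positive,Negative,Negative,Yes,VUS,VUS,0.571,0.503
S11,32,Female,Yes,No,0,Unknown,Positive,Unknown,Right Breast,Positive,Positive,Negative,Negative,Positive,Yes,VUS,VUS,0.425,0.499
S12,40,Female,No,No,0,30,Positive,Grade 2,Both Breast,Positive,Positive,Positive,Negative,Positive,Yes,VUS,VUS,0.425,0.510
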