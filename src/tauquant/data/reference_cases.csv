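case_id,age,sex,braak_stage,braak_group,pmd_hours,fixation_weeks,clinical_note
1,68,M,0,control,54,7,Cognitively normal
2,55,M,0,control,41,11,Cognitively normal
3,70,M,0,control,72,6,Cognitively normal
4,78,F,0,control,34,8,Cognitively normal
5,73,M,0,control,25,9,Cognitively normal
6,96,F,2,I_II,114,49,Mild dementia
7,77,M,2,I_II,83,15,Cognitively normal
8,94,F,2,I_II,15,9,Cognitively normal
9,70,M,2,I_II,39,7,Multiple psychiatric and physical problems
10,74,F,1,I_II,49,10,Cognitively normal
11,75,M,4,III_IV,82,23,Cognitively normal
12,79,M,3,III_IV,13,15,Cognitively normal
13,81,M,3,III_IV,82,8,Unspecified dementia
14,98,F,3,III_IV,59,8,Cognitively normal
15,91,M,3,III_IV,48,9,Moderate cognitive impairment and vascular disease
16,84,F,6,V_VI,47,16,"Severe dementia, anxiety and depression"
17,77,F,6,V_VI,63,5,Dementia
18,80,F,6,V_VI,32,16,Dementia
19,86,F,6,V_VI,5,6,Dementia
20,89,F,6,V_VI,85,8,Dementia
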