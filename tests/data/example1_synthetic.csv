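study_id,g,n1,n2
study_1,0.29994045701342448,10,10
study_2,0.03774386352738341,15,15
study_3,0.88814241841925634,10,20
study_4,-0.49860744641408666,5,5
study_5,-0.42459869677752859,10,10
study_6,-0.10337823958826331,15,25
study_7,-0.82728501925848352,5,5
study_8,0.078765602154841019,10,10
study_9,0.14965644861934801,15,25
study_10,0.11560472949496885,10,20
study_11,1.6203124342159219,5,15
study_12,0.76529689705288206,10,20
study_13,0.32148748918734404,20,20
study_14,0.74337362578243549,5,15
study_15,0.9766604756313797,10,10
study_16,-0.14029649910208228,10,30
study_17,0.80183026704794835,20,20
study_18,0.76316866241040848,10,20
study_19,-0.33241576922098887,10,30
study_20,0.28655849310797626,10,20
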