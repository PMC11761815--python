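study_id,g,n1,n2
study_1,0.8803954574255568,5,15
study_2,0.8222580941035178,15,25
study_3,-0.26254625799062375,10,10
study_4,0.66681622592213441,10,10
study_5,0.034664735738309978,5,15
study_6,1.0228891567536098,10,10
study_7,0.84797132915930673,20,20
study_8,0.49377919859699976,5,5
study_9,0.96064990395762062,15,25
study_10,0.36518272781294359,10,30
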