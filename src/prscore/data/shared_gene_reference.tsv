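gene	diseases
TSBP1-AS1	Asthma,Celiac_disease,Colitis,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
GSDMB	Asthma,Colitis,Crohn_disease,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
TNXB	Celiac_disease,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,SLE,T1DM,Thyroid_disease
IL2RA	Asthma,Colitis,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,SLE,T1DM
SH2B3	Asthma,Celiac_disease,Psoriasis,Rheumatoid_arthritis,SLE,T1DM,Thyroid_disease
IRF5	Asthma,Colitis,Crohn_disease,Psoriasis,Rheumatoid_arthritis,SLE,Thyroid_disease
TSBP1	Asthma,Celiac_disease,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
TAP2	Asthma,Celiac_disease,Colitis,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
BACH2	Asthma,Multiple_sclerosis,Rheumatoid_arthritis,SLE,T1DM,Thyroid_disease
HLA-DQB1	Asthma,Celiac_disease,Colitis,Rheumatoid_arthritis,T1DM,Thyroid_disease
HLA-DRA	Asthma,Celiac_disease,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,T1DM
RBFOX1	Asthma,Celiac_disease,Colitis,Crohn_disease,Psoriasis,T1DM
PTCHD1-AS	Asthma,Celiac_disease,Colitis,Psoriasis,Rheumatoid_arthritis,T1DM
LOC124901301	Asthma,Celiac_disease,Multiple_sclerosis,SLE,T1DM,Thyroid_disease
HLA-DPB1	Asthma,Celiac_disease,Multiple_sclerosis,Rheumatoid_arthritis,T1DM,Thyroid_disease
CSMD1	Celiac_disease,Colitis,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
HCG20	Celiac_disease,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,T1DM,Thyroid_disease
BTNL2	Celiac_disease,Colitis,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,T1DM
ERAP1	Asthma,Crohn_disease,Psoriasis,Rheumatoid_arthritis,SLE,Thyroid_disease
CNTN5	Asthma,Crohn_disease,Multiple_sclerosis,Rheumatoid_arthritis,T1DM,Thyroid_disease
ZMIZ1	Celiac_disease,Multiple_sclerosis,Psoriasis,Rheumatoid_arthritis,SLE,T1DM
CLEC16A	Asthma,Multiple_sclerosis,Rheumatoid_arthritis,SLE,T1DM,Thyroid_disease
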