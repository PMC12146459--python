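participant_id,drug_class,analysis_days,covered_days,pdc_5y,adherent_5y
F01,metformin,1826,1826,1.0000000000,1
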