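participant_id,drug_class,n_records,single_record_flag,eligible,index_date,censor_date,event
F01,metformin,69,0,1,2013-01-05,2019-12-31,study_end
F02,metformin,8,0,1,2014-03-01,2015-09-07,discontinued
F03,metformin,1,1,0,2013-05-10,2013-06-16,discontinued
F04,metformin,5,0,1,2013-01-10,2013-05-01,discontinued
F05,metformin,3,0,1,2013-02-01,2013-05-23,switched
F05,sulfonylurea,10,0,1,2013-06-01,2014-04-27,discontinued
F06,metformin,25,0,1,2013-01-20,2015-06-30,death
F07,metformin,2,0,1,2013-01-01,2014-02-07,discontinued
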