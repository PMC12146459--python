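participant_id,drug_class,period_index,period_start,period_end,analysis_days,covered_days,pdc,adherent,outcome
F01,metformin,1,2013-01-05,2014-01-05,365,365,1.0000000000,1,full
F01,metformin,2,2014-01-05,2015-01-05,365,365,1.0000000000,1,full
F01,metformin,3,2015-01-05,2016-01-05,365,365,1.0000000000,1,full
F01,metformin,4,2016-01-05,2017-01-05,366,366,1.0000000000,1,full
F01,metformin,5,2017-01-05,2018-01-05,365,365,1.0000000000,1,full
F02,metformin,1,2014-03-01,2015-03-01,365,185,0.5068493151,0,full
F02,metformin,2,2015-03-01,2016-03-01,191,111,0.5811518325,0,discontinued
F04,metformin,1,2013-01-10,2014-01-10,112,111,0.9910714286,1,discontinued
F05,metformin,1,2013-02-01,2014-02-01,112,111,0.9910714286,1,switched
F05,sulfonylurea,1,2013-06-01,2014-06-01,331,330,0.9969788520,1,discontinued
F06,metformin,1,2013-01-20,2014-01-20,365,365,1.0000000000,1,full
F06,metformin,2,2014-01-20,2015-01-20,365,365,1.0000000000,1,full
F06,metformin,3,2015-01-20,2016-01-20,162,162,1.0000000000,1,died_or_study_end
F07,metformin,1,2013-01-01,2014-01-01,365,37,0.1013698630,0,full
F07,metformin,2,2014-01-01,2015-01-01,38,37,0.9736842105,1,discontinued
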