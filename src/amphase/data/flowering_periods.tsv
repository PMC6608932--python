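year	start_day	end_day
1999	165	178
2009	156	170
2010	170	180
2011	147	157
2012	153	169
2013	168	183
2014	150	161
2015	156	167
2016	168	177
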