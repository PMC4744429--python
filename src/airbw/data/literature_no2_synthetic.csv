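study_id,effect_g_per_10ppb,n,include
synthA_2004,-10.4,5000,1
synthB_2005,-16.2,12000,1
synthC_2007,-21.0,3500,1
synthD_2008,-8.0,25000,1
synthE_2009,-27.4,1800,1
synthF_2010,-12.9,60000,1
synthG_2011,-18.5,9000,1
synthH_2012,-5.3,15000,1
synthMeta_2012,-14.1,120000,0
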