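strategy,label,cost_per_entry,n_entries,reps_per_site,rows_per_site,n_sites
PS,making testcrosses,10,1492,1,1,1
PS,stage I multi-location yield trials,5,1492,2,2,4
GS,making testcrosses,10,855,1,1,1
GS,phenotyping training set in stage I multi-location yield trials,5,855,2,2,4
GS,genotyping all lines,10,1492,1,1,1
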