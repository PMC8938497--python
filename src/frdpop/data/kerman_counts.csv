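stratum_id,domain,n1,n2,r
city_pooled,city,283,272,83
suburb_pooled,suburb,635,505,103
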