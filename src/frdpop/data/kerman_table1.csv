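variable,interest,reference,city_interest,city_reference,suburb_interest,suburb_reference
sex,female,male,114,279,189,698
age_class,adult,pup_young,354,39,766,121
body_condition,ideal_overweight,thin_emaciated,387,6,723,164
social_org,single,pair,65,65,156,178
social_org,pack,pair,263,65,553,178
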