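group,category,count
environmental,availability,7
environmental,marketing,2
environmental,pricing,4
environmental,drink_driving,13
workplace,workplace,4
health_sector,health_sector,3
community,youth_development,8
community,school_based,8
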