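treatment_id,age_group,phototype,epidermis_pre,epidermis_post,dermis_pre,dermis_post,leps_lepi_pre,leps_lepi_post
placebo,40-75,II-III,0.1358,0.13505,1.49635,1.57155,0.924757,1.042922
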