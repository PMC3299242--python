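treatment_id,age_group,phototype,epidermis_pre,epidermis_post,dermis_pre,dermis_post,leps_lepi_pre,leps_lepi_post
P63,40-75,II-III,0.117,0.135,1.537,1.719,1.149,1.574
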