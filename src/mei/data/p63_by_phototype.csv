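treatment_id,age_group,phototype,epidermis_pre,epidermis_post,dermis_pre,dermis_post,leps_lepi_pre,leps_lepi_post
P63,40-75,2,0.114625,0.129938,1.605313,1.768063,1.198661,1.580802
P63,40-75,3,0.12,0.141,1.460571,1.644214,1.092623,1.567998
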