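treatment_id,age_group,phototype,epidermis_pre,epidermis_post,dermis_pre,dermis_post,leps_lepi_pre,leps_lepi_post
P63,40-49,II-III,0.114,0.135333,1.8585,1.901,1.204593,1.457353
P63,50-59,II-III,0.11675,0.1345,1.386313,1.740563,1.096062,1.398047
P63,60-75,II-III,0.12025,0.136125,1.367625,1.506625,1.213842,1.510156
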