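study_id,species,sex,repro_state,parameter,value,unit,n_birds,dispersion_type,dispersion_value,citation,provenance
tab4-imm-gizzard,chicken,female,immature,rel_wt_g_100g.gizzard,3.06,g/100g,,SEM,0.58,SM1,table=tab4;row=Gizzard;col=Immature females;n_studies=11
tab4-lay-gizzard,chicken,female,laying,rel_wt_g_100g.gizzard,3.21,g/100g,,SEM,1.10,SM1,table=tab4;row=Gizzard;col=Laying hens;n_studies=7
tab4-imm-kidneys,chicken,female,immature,rel_wt_g_100g.kidneys,0.65,g/100g,,SEM,0.14,SM1,table=tab4;row=Kidneys;col=Immature females;n_studies=8
tab4-lay-kidneys,chicken,female,laying,rel_wt_g_100g.kidneys,0.80,g/100g,,SEM,0.098,SM1,table=tab4;row=Kidneys;col=Laying hens;n_studies=5
tab4-imm-liver,chicken,female,immature,rel_wt_g_100g.liver,2.04,g/100g,,SEM,0.19,SM1,table=tab4;row=Liver;col=Immature females;n_studies=12
tab4-lay-liver,chicken,female,laying,rel_wt_g_100g.liver,2.33,g/100g,,SEM,0.10,SM1,table=tab4;row=Liver;col=Laying hens;n_studies=23
tab4-imm-si,chicken,female,immature,rel_wt_g_100g.small_intestine,4.15,g/100g,,SEM,0.87,SM1,table=tab4;row=Small intestine;col=Immature females;n_studies=3
tab4-lay-si,chicken,female,laying,rel_wt_g_100g.small_intestine,3.39,g/100g,,SEM,1.22,SM1,table=tab4;row=Small intestine;col=Laying hens;n_studies=3
tab4-imm-spleen,chicken,female,immature,rel_wt_g_100g.spleen,0.176,g/100g,,SEM,0.025,SM1,table=tab4;row=Spleen;col=Immature females;n_studies=8
tab4-lay-spleen,chicken,female,laying,rel_wt_g_100g.spleen,0.160,g/100g,,SEM,0.022,SM1,table=tab4;row=Spleen;col=Laying hens;n_studies=8
tab4-imm-ovary,chicken,female,immature,rel_wt_g_100g.ovary,0.046,g/100g,,SEM,0.015,SM1,table=tab4;row=Ovary;col=Immature females;n_studies=4
tab4-lay-ovary,chicken,female,laying,rel_wt_g_100g.ovary,2.42,g/100g,,SEM,0.19,SM1,table=tab4;row=Ovary;col=Laying hens;n_studies=15
tab4-imm-oviduct,chicken,female,immature,rel_wt_g_100g.oviduct,0.046,g/100g,,SEM,0.024,SM1,table=tab4;row=Oviduct;col=Immature females;n_studies=2
tab4-lay-oviduct,chicken,female,laying,rel_wt_g_100g.oviduct,2.80,g/100g,,SEM,0.20,SM1,table=tab4;row=Oviduct;col=Laying hens;n_studies=9
tab4-imm-livcells,chicken,female,immature,liver_cells_per_g,1.417e9,1/g,,SEM,0.192e9,DNA per g liver at 2.15 pg per cell,table=tab4;row=Liver cell number x10^9 per g;col=Immature females;n_studies=4
tab4-lay-livcells,chicken,female,laying,liver_cells_per_g,1.127e9,1/g,,SEM,0.113e9,DNA per g liver at 2.15 pg per cell,table=tab4;row=Liver cell number x10^9 per g;col=Laying hens;n_studies=4
tab4-imm-livvol,chicken,female,immature,liver_cell_volume_fL,526,fL,,SEM,112,assumes liver is 90% cells,table=tab4;row=Liver cell volume fL;col=Immature females;n_studies=4;flag=stored_not_asserted
tab4-lay-livvol,chicken,female,laying,liver_cell_volume_fL,682,fL,,SEM,138,assumes liver is 90% cells,table=tab4;row=Liver cell volume fL;col=Laying hens;n_studies=4;flag=stored_not_asserted
tab4-imm-livlipid,chicken,female,immature,liver_lipid_g_100g,4.4,g/100g,,SEM,0.75,sexually immature female and male chickens,table=tab4;row=Lipid g 100g-1;col=Immature females;n_studies=4
tab4-lay-livlipid,chicken,female,laying,liver_lipid_g_100g,13.0,g/100g,,SEM,1.54,ref47 ref57 ref11,table=tab4;row=Lipid g 100g-1;col=Laying hens;n_studies=3
tab4-br-gizzard,chicken,mixed,broiler_juvenile,rel_wt_g_100g.gizzard,2.932,g/100g,,SEM,0.64,SM1,table=tab4;row=Gizzard (footnote broilers);n_studies=6
tab4-br-si,chicken,mixed,broiler_juvenile,rel_wt_g_100g.small_intestine,3.59,g/100g,,SEM,0.36,SM1,table=tab4;row=Small intestine (footnote broilers);n_studies=7
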