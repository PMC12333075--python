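plot_id,species,cover_percent,trophic_level
min-000,Comarum palustre,18.4230910869,minerotrophic
min-000,Filipendula ulmaria,34.2917645929,minerotrophic
min-000,Litter,4.68986813131,minerotrophic
min-000,Menyanthes trifoliata,0,minerotrophic
min-000,Sphagnum angustifolium,37.8305353055,minerotrophic
min-000,Sphagnum fallax,4.76474088342,minerotrophic
min-001,Comarum palustre,7.60326509724,minerotrophic
min-001,Filipendula ulmaria,24.5456347465,minerotrophic
min-001,Litter,38.7845275043,minerotrophic
min-001,Menyanthes trifoliata,3.50721181349,minerotrophic
min-001,Sphagnum angustifolium,0,minerotrophic
min-001,Sphagnum fallax,25.5593608385,minerotrophic
min-002,Comarum palustre,80.5874247902,minerotrophic
min-002,Filipendula ulmaria,12.8013776971,minerotrophic
min-002,Litter,2.39057407317,minerotrophic
min-002,Menyanthes trifoliata,2.56287939411,minerotrophic
min-002,Sphagnum angustifolium,0,minerotrophic
min-002,Sphagnum fallax,1.65774404546,minerotrophic
min-003,Comarum palustre,26.4018732838,minerotrophic
min-003,Filipendula ulmaria,21.8475051193,minerotrophic
min-003,Litter,13.2925471845,minerotrophic
min-003,Menyanthes trifoliata,5.97967217764,minerotrophic
min-003,Sphagnum angustifolium,25.0176506554,minerotrophic
min-003,Sphagnum fallax,7.46075157942,minerotrophic
min-004,Comarum palustre,3.04548486594,minerotrophic
min-004,Filipendula ulmaria,14.2711232139,minerotrophic
min-004,Litter,33.0872463898,minerotrophic
min-004,Menyanthes trifoliata,39.8997850479,minerotrophic
min-004,Sphagnum angustifolium,3.06539132301,minerotrophic
min-004,Sphagnum fallax,6.63096915941,minerotrophic
min-005,Comarum palustre,0,minerotrophic
min-005,Filipendula ulmaria,1.85235001998,minerotrophic
min-005,Litter,3.23489579201,minerotrophic
min-005,Menyanthes trifoliata,14.687871477,minerotrophic
min-005,Sphagnum angustifolium,33.0914828268,minerotrophic
min-005,Sphagnum fallax,47.1333998842,minerotrophic
omb-000,Calluna vulgaris,0,ombrotrophic
omb-000,Litter,34.3085009937,ombrotrophic
omb-000,Rubus chamaemorus,33.3736933496,ombrotrophic
omb-000,Sphagnum cuspidatum,11.014018501,ombrotrophic
omb-000,Sphagnum fuscum,11.7627181989,ombrotrophic
omb-000,Sphagnum rubellum,9.54106895683,ombrotrophic
omb-001,Calluna vulgaris,7.87224546496,ombrotrophic
omb-001,Litter,29.6411968012,ombrotrophic
omb-001,Rubus chamaemorus,3.1436589387,ombrotrophic
omb-001,Sphagnum cuspidatum,7.87131605164,ombrotrophic
omb-001,Sphagnum fuscum,44.0298862195,ombrotrophic
omb-001,Sphagnum rubellum,7.44169652404,ombrotrophic
omb-002,Calluna vulgaris,5.80483108321,ombrotrophic
omb-002,Litter,6.22820684513,ombrotrophic
omb-002,Rubus chamaemorus,10.9021481652,ombrotrophic
omb-002,Sphagnum cuspidatum,45.7587683717,ombrotrophic
omb-002,Sphagnum fuscum,3.73540099072,ombrotrophic
omb-002,Sphagnum rubellum,27.5706445441,ombrotrophic
omb-003,Calluna vulgaris,3.11520329314,ombrotrophic
omb-003,Litter,14.4422729992,ombrotrophic
omb-003,Rubus chamaemorus,12.3829701392,ombrotrophic
omb-003,Sphagnum cuspidatum,35.8546249674,ombrotrophic
omb-003,Sphagnum fuscum,34.2049286011,ombrotrophic
omb-003,Sphagnum rubellum,0,ombrotrophic
omb-004,Calluna vulgaris,36.6310937958,ombrotrophic
omb-004,Litter,16.2442551543,ombrotrophic
omb-004,Rubus chamaemorus,38.9524841835,ombrotrophic
omb-004,Sphagnum cuspidatum,5.65805443405,ombrotrophic
omb-004,Sphagnum fuscum,2.51411243224,ombrotrophic
omb-004,Sphagnum rubellum,0,ombrotrophic
omb-005,Calluna vulgaris,31.7409619868,ombrotrophic
omb-005,Litter,7.50398754761,ombrotrophic
omb-005,Rubus chamaemorus,0.870030775591,ombrotrophic
omb-005,Sphagnum cuspidatum,7.09524614798,ombrotrophic
omb-005,Sphagnum fuscum,20.6919444854,ombrotrophic
omb-005,Sphagnum rubellum,32.0978290566,ombrotrophic
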