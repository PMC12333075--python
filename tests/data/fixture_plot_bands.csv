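wavelength_nm,min-000,min-001,min-002,min-003,min-004,min-005,omb-000,omb-001,omb-002,omb-003,omb-004,omb-005
490,0.0784614912153,0.111154374823,0.0691409248897,0.0833281197075,0.104641979571,0.0725716175947,0.108502856617,0.10732940464,0.0769430142372,0.0829946752428,0.0883361194902,0.0881904424817
560,0.133387026905,0.156633326133,0.128373893836,0.134260936762,0.155631286341,0.111946461277,0.150274049802,0.1408968432,0.110051984484,0.116027811804,0.132611268087,0.123110019072
665,0.118976413839,0.170620309138,0.078753841451,0.122400488337,0.140275143742,0.135945528237,0.174826458867,0.186939262283,0.140642811031,0.149446483853,0.142409100949,0.160258789644
705,0.230092644608,0.246372936872,0.196455509799,0.219670343038,0.225488004702,0.201365930817,0.244174256456,0.240540711787,0.200456655233,0.205848807639,0.236202375126,0.22801139343
740,0.362868469203,0.335658076402,0.363111996814,0.34221405353,0.342569370325,0.2750834749,0.319579508793,0.288612721978,0.257836552811,0.263086235206,0.329806755164,0.288393589465
783,0.421925583805,0.382903047013,0.431859161696,0.401597508603,0.406483213246,0.329012285002,0.370100258728,0.332935288735,0.305841441855,0.30984254771,0.384374962059,0.336169587692
842,0.435429349627,0.403104834276,0.436328559869,0.415468200095,0.422219791941,0.353405015379,0.393736773732,0.359268682366,0.333235228316,0.335970876425,0.398704304509,0.357015424422
865,0.444708600599,0.414504661203,0.44282425529,0.42457352236,0.431824289454,0.366127659027,0.405764086186,0.372710862747,0.347173751066,0.349134234656,0.407784461886,0.368344880465
1610,0.423126225446,0.431310010432,0.416039406455,0.415798612132,0.440925378357,0.36730209947,0.432489837155,0.391029462179,0.349993408211,0.357192423197,0.411213264841,0.365551743499
2190,0.405908820771,0.416654511149,0.385168593851,0.392829893165,0.416179369519,0.340945572523,0.395365877927,0.362468004492,0.308177000396,0.317056111759,0.378493864953,0.339420780633
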