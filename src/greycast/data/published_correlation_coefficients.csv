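block,indicator,Resident Consumption,Energy Consumption,Education Funds,Wage Level,Research Input
grey,Accident death toll,0.766539,0.669142,0.742253,0.749791,0.769856
grey,Mortality of 100 million yuan,0.729998,0.623648,0.722355,0.723761,0.757859
grey,Mortality per 100000 workers,0.754780,0.647696,0.735713,0.741025,0.766227
grey,Comprehensive accident index,0.750439,0.646829,0.733440,0.738192,0.764647
pearson,Accident death toll,0.956225,0.955454,0.963937,0.962162,0.963653
pearson,Mortality of 100 million yuan,0.797445,0.796760,0.827531,0.818164,0.862573
pearson,Mortality per 100000 workers,0.865659,0.870746,0.898157,0.876959,0.914696
pearson,Comprehensive accident index,0.873110,0.874320,0.896542,0.885761,0.916307
composite,Accident death toll,0.861382,0.810398,0.853095,0.855976,0.862655
composite,Mortality of 100 million yuan,0.763721,0.793110,0.774943,0.770962,0.777309
composite,Mortality per 100000 workers,0.810220,0.801196,0.816935,0.808992,0.818486
composite,Comprehensive accident index,0.811774,0.801568,0.814991,0.811977,0.819484
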