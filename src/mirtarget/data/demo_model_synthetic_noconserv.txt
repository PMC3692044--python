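registry_version=1
label=demo model fitted on synthetic data, conservation-free variant
intercept=-0.2394058523147506
training_r2=0.10207572151210076
coef.dg_duplex=0.011868235622052702
coef.dg_open=0.012143797880908106
coef.dg_seed_binding=0.019451754127254875
coef.prob_exact=0.21619856802873133
coef.au_content=-0.2885833957171937
coef.utr_position=0.00011261941084081329
coef.three_prime_pairing=-0.024295734937425435
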