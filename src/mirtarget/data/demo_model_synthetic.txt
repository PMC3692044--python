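registry_version=1
label=demo model fitted on synthetic data (not a published model)
intercept=0.023325879058050034
training_r2=0.1676288200939554
coef.dg_duplex=0.011984842877446793
coef.dg_open=0.011276765436623653
coef.dg_seed_binding=0.0186225197218449
coef.prob_exact=0.22275844805181194
coef.bls=-0.07605390472304473
coef.phylop_score=-0.040622560801731676
coef.au_content=-0.29271974664223593
coef.utr_position=0.0001052005547161897
coef.three_prime_pairing=-0.02464602606591107
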