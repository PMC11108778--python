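cohort	n_individuals
Uganda	1391
Burkina Faso	353
South Africa	755
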