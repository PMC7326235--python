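# reproductive ageing score model parameters (published development fit)
mu_a.shift = 0.7
mu_a.c4 = -0.00047
mu_a.c3 = 0.009
mu_a.c2 = -0.0307
mu_a.c1 = 0.086
mu_a.c0 = -2.317
mu_b.b2 = 0.0047
mu_b.b1 = -0.0866
mu_b.b0 = -7.646
smoking_offset = 2
unilateral_oophorectomy_offset = 1
modifiers_enabled = 1
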