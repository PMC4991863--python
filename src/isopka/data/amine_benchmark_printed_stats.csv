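group,stat,PM6-D3H+/SMD,PM6-D3H+/SMD*,PM6/SMD*,PM6/COSMO*
secondary_amine,MAD,0.9,0.6,1.0,0.5
secondary_amine,MaxAD,1.6,1.4,1.4,1.0
tertiary_amine,MAD,2.5,1.9,2.7,1.0
tertiary_amine,MaxAD,3.7,3.2,4.5,2.1
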