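reference,pka_ref,exp,PM6-D3H+/SMD,PM6-D3H+/SMD*,PM6/SMD*,PM6/COSMO*
Tri-ethylamine,10.7,4.2,-4.3,-3.6,5.9,-0.2
Benzylpyrrolidene,8.9,4.2,-1.9,-1.5,7.8,0.1
Heliotridane,11.4,4.2,-1.6,-1.8,8.7,0.7
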