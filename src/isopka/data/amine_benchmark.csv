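name,group,exp,PM6-D3H+/SMD,PM6-D3H+/SMD*,PM6/SMD*,PM6/COSMO*
Morpholine,secondary_amine,8.4,7.3,7.8,7.2,7.9
Piperidine,secondary_amine,11.2,10.9,11.3,10.8,10.9
Piperazine,secondary_amine,9.8,8.8,9.0,8.4,9.1
Pyrrolidine,secondary_amine,11.3,11.3,11.1,10.6,11.3
Diallylamine,secondary_amine,9.3,8.0,8.7,7.9,8.3
Diisopropylamine,secondary_amine,11.0,12.6,12.4,11.7,11.4
N-methyl morpholine,tertiary_amine,7.4,4.9,5.8,4.6,7.4
Quinuclidine,tertiary_amine,11.0,8.1,8.7,7.5,9.4
DABCO,tertiary_amine,8.8,5.1,5.6,4.3,6.7
N-Ethylpyrrolidine,tertiary_amine,10.4,9.0,9.5,8.6,10.4
Triallylamine,tertiary_amine,8.3,4.8,6.9,5.2,6.9
Diisopropylmethylamine,tertiary_amine,10.5,11.8,12.4,11.3,11.5
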