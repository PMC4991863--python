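name,site_class,pka_ref,is_default,provenance
Pyridine,pyridine,5.2,1,benchmark set experimental compilation
Ethanol,alcohol,15.9,1,benchmark set experimental compilation
Acetic acid,carboxylic_acid,4.8,1,benchmark set experimental compilation
Diethylamine,secondary_amine,11.1,1,amine benchmark experimental value
Tri-ethylamine,tertiary_amine,10.7,1,amine benchmark experimental value
Quinuclidine,tertiary_amine,11.0,0,amine benchmark experimental value; alternative anchor for bicyclic tertiary amines
Benzylpyrrolidene,tertiary_amine,8.9,0,literature estimate (not measured); drug-like anchor
Heliotridane,tertiary_amine,11.4,0,literature value; drug-like anchor
Methylamine,primary_amine,10.6,1,inferred; not in the curated anchor compilation
Phenol,phenol,10.0,1,inferred; not in the curated anchor compilation
Benzoic acid,benzoic_acid,4.2,1,inferred; not in the curated anchor compilation
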