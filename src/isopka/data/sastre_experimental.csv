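name,group,exp,is_reference
Pyridine,pyridine,5.2,1
2-Methylpyridine,pyridine,6.0,0
3-Methylpyridine,pyridine,5.7,0
4-Methylpyridine,pyridine,6.0,0
"2,3-Dimethylpyridine",pyridine,6.6,0
"2,4-Dimethylpyridine",pyridine,7.0,0
3-Fluoropyridine,pyridine,3.0,0
3-Cyanopyridine,pyridine,1.5,0
Ethanol,alcohol,15.9,1
Methanol,alcohol,15.5,0
Propanol,alcohol,16.1,0
i-Propanol,alcohol,17.1,0
2-Butanol,alcohol,17.6,0
tert-butanol,alcohol,19.2,0
Acetic acid,carboxylic_acid,4.8,1
Formic,carboxylic_acid,3.8,0
Benzoic,carboxylic_acid,4.2,0
Hexanoic,carboxylic_acid,4.8,0
Propanoic,carboxylic_acid,4.9,0
Pentanoic,carboxylic_acid,4.9,0
Trimethylacetic,carboxylic_acid,5.1,0
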