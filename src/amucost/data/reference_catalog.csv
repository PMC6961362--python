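composition,n_products
colistin|amoxicillin,12
colistin|ampicillin,12
colistin|neomycin,8
colistin|gentamicin,2
colistin|apramycin,1
tylosin|gentamicin,5
tylosin|amoxicillin,2
tylosin|streptomycin,1
enrofloxacin,12
flumequine,9
tilmicosin,6
erythromycin,2
norfloxacin,2
tylosin,1
colistin,2
colistin|tylosin,3
colistin|spiramycin,2
colistin|enrofloxacin,1
colistin|erythromycin,1
colistin|oxytetracycline,9
colistin|doxycycline,1
colistin|lincomycin,1
colistin|sulfadimethoxine,1
doxycycline|tylosin,6
doxycyline|tilmicosin,1
erythromycin|sulphamethoxazole,2
erythromycin|oxytetracycline,3
kitasamycin|thiamphenicol,1
oxytetracycline|spiramycin,3
oxytetracycline|tylosin,2
tylosin|sulfadimidine,3
tylosin|tetracycline,2
tylosin|sulfachloropyridazine,1
tylosin|sulfamethazine,1
tylosin|sulphamethoxazole,1
oxytetracycline,9
oxytetracycline|sulfadimidine,1
oxytetracycline|thiamphenicol,1
doxycycline,5
doxycycline|florfenicol,3
doxycycline|lincomycin,1
florfenicol,8
lincomycin,2
cephalexin,1
cefadroxil,1
sulphathiazole,1
sulfamethoxypyridazine|tetracycline,1
sulphamethoxazole|thiamphenicol,1
lincomycin|spectinomycin,6
doxycycline|gentamicin,5
doxycycline|neomycin,1
doxycycline|ampicillin,1
oxytetracycline|streptomycin,5
oxytetracycline|neomycin,4
ampicillin|sulfadimethoxine,1
gentamicin|sulfadimidine,1
streptomycin|sulphamethoxazole,1
amoxicillin,7
neomycin,3
ampicillin,1
streptomycin,1
sulfadimethoxine|trimethoprim,4
sulfadiazine|trimethoprim,1
sulfadimidine|trimethoprim,1
sulphamethoxazole|trimethoprim,1
doxycycline|tiamulin,1
colistin|trimethoprim,3
josamycin|trimethoprim,1
spiramycin|trimethoprim,1
colistin|enramycin,1
trimethoprim,2
methenamine,1
gentamicin|trimethoprim,1
neomycin|trimethoprim,1
tylosin|trimethoprim|sulfadiazine|sulphamethoxazole,1
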