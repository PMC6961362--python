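name,alias,who_category,aai_class
colistin,,HIGHEST_PRIORITY,polymyxin
tylosin,tylosine,HIGHEST_PRIORITY,macrolide
tilmicosin,,HIGHEST_PRIORITY,macrolide
erythromycin,erythromycine,HIGHEST_PRIORITY,macrolide
spiramycin,spiramycine,HIGHEST_PRIORITY,macrolide
kitasamycin,,HIGHEST_PRIORITY,macrolide
josamycin,josamycine,HIGHEST_PRIORITY,macrolide
enrofloxacin,,HIGHEST_PRIORITY,quinolone
norfloxacin,,HIGHEST_PRIORITY,quinolone
flumequine,,HIGHEST_PRIORITY,quinolone
amoxicillin,amoxycillin,HIGH_PRIORITY,aminopenicillin
ampicillin,,HIGH_PRIORITY,aminopenicillin
neomycin,neomycine,HIGH_PRIORITY,aminoglycoside
gentamicin,gentamycin,HIGH_PRIORITY,aminoglycoside
apramycin,,HIGH_PRIORITY,aminoglycoside
streptomycin,streptomycine,HIGH_PRIORITY,aminoglycoside
spectinomycin,,HIGH_PRIORITY,aminoglycoside
oxytetracycline,,HIGHLY_IMPORTANT,tetracycline
doxycycline,doxycyline,HIGHLY_IMPORTANT,tetracycline
tetracycline,,HIGHLY_IMPORTANT,tetracycline
lincomycin,lincomycine,HIGHLY_IMPORTANT,lincosamide
florfenicol,,HIGHLY_IMPORTANT,amphenicol
thiamphenicol,,HIGHLY_IMPORTANT,amphenicol
cephalexin,cefalexin,HIGHLY_IMPORTANT,cephalosporin
cefadroxil,cephadroxil,HIGHLY_IMPORTANT,cephalosporin
sulfadimethoxine,,HIGHLY_IMPORTANT,sulfonamide
sulfadiazine,,HIGHLY_IMPORTANT,sulfonamide
sulfadimidine,,HIGHLY_IMPORTANT,sulfonamide
sulfamethazine,,HIGHLY_IMPORTANT,sulfonamide
sulfamethoxazole,,HIGHLY_IMPORTANT,sulfonamide
sulfachloropyridazine,,HIGHLY_IMPORTANT,sulfonamide
sulfathiazole,,HIGHLY_IMPORTANT,sulfonamide
sulfamethoxypyridazine,,HIGHLY_IMPORTANT,sulfonamide
trimethoprim,,OTHER,diaminopyrimidine
methenamine,hexamine,OTHER,other
tiamulin,,OTHER,pleuromutilin
enramycin,,OTHER,other
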