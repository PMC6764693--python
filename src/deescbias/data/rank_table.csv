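drug,rank,is_beta_lactam,is_macrolide
penicillin,1,1,0
amoxicillin,1,1,0
tetracycline,1,0,0
doxycycline,1,0,0
cefazolin,2,1,0
cephalexin,2,1,0
cefuroxime,2,1,0
cefaclor,2,1,0
co-amoxiclav,2,1,0
co-trimoxazole,2,0,0
clindamycin,2,0,0
erythromycin,2,0,1
azithromycin,2,0,1
clarithromycin,2,0,1
ceftriaxone,3,1,0
cefotaxime,3,1,0
ceftazidime,3,1,0
cefepime,3,1,0
ciprofloxacin,3,0,0
levofloxacin,3,0,0
moxifloxacin,3,0,0
gentamicin,3,0,0
tobramycin,3,0,0
amikacin,3,0,0
piperacillin-tazobactam,3,1,0
meropenem,3,1,0
imipenem,3,1,0
ertapenem,3,1,0
vancomycin,3,0,0
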