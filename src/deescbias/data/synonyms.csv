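synonym,canonical
amoxicillin-clavulanate,co-amoxiclav
amoxicillin/clavulanate,co-amoxiclav
amoxicillin-clavulanic acid,co-amoxiclav
augmentin,co-amoxiclav
co-amoxi-clav,co-amoxiclav
trimethoprim-sulfamethoxazole,co-trimoxazole
trimethoprim/sulfamethoxazole,co-trimoxazole
cotrimoxazole,co-trimoxazole
clindamycine,clindamycin
doxycyclin,doxycycline
piperacillin/tazobactam,piperacillin-tazobactam
tazocin,piperacillin-tazobactam
benzylpenicillin,penicillin
penicillin g,penicillin
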