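# dictionary_version=1.0
normalized_name,ingredient,classes
lipitor,atorvastatin,statin
atorvastatin,atorvastatin,statin
zocor,simvastatin,statin
simvastatin,simvastatin,statin
crestor,rosuvastatin,statin
rosuvastatin,rosuvastatin,statin
pravachol,pravastatin,statin
pravastatin,pravastatin,statin
metoprolol,metoprolol,beta_blocker
lopressor,metoprolol,beta_blocker
toprol,metoprolol,beta_blocker
atenolol,atenolol,beta_blocker
tenormin,atenolol,beta_blocker
propranolol,propranolol,beta_blocker
inderal,propranolol,beta_blocker
lisinopril,lisinopril,ace_inhibitor
prinivil,lisinopril,ace_inhibitor
zestril,lisinopril,ace_inhibitor
enalapril,enalapril,ace_inhibitor
vasotec,enalapril,ace_inhibitor
ramipril,ramipril,ace_inhibitor
altace,ramipril,ace_inhibitor
omeprazole,omeprazole,proton_pump_inhibitor
prilosec,omeprazole,proton_pump_inhibitor
esomeprazole,esomeprazole,proton_pump_inhibitor
nexium,esomeprazole,proton_pump_inhibitor
pantoprazole,pantoprazole,proton_pump_inhibitor
protonix,pantoprazole,proton_pump_inhibitor
sertraline,sertraline,ssri
zoloft,sertraline,ssri
fluoxetine,fluoxetine,ssri
prozac,fluoxetine,ssri
citalopram,citalopram,ssri
celexa,citalopram,ssri
escitalopram,escitalopram,ssri
lexapro,escitalopram,ssri
metformin,metformin,biguanide
glucophage,metformin,biguanide
ibuprofen,ibuprofen,nsaid
advil,ibuprofen,nsaid
motrin,ibuprofen,nsaid
naproxen,naproxen,nsaid
aleve,naproxen,nsaid
warfarin,warfarin,antithrombotic
coumadin,warfarin,antithrombotic
clopidogrel,clopidogrel,antithrombotic
plavix,clopidogrel,antithrombotic
levothyroxine,levothyroxine,thyroid_hormone
synthroid,levothyroxine,thyroid_hormone
loratadine,loratadine,antihistamine
claritin,loratadine,antihistamine
cetirizine,cetirizine,antihistamine
zyrtec,cetirizine,antihistamine
donepezil,donepezil,cholinesterase_inhibitor
aricept,donepezil,cholinesterase_inhibitor
rivastigmine,rivastigmine,cholinesterase_inhibitor
exelon,rivastigmine,cholinesterase_inhibitor
galantamine,galantamine,cholinesterase_inhibitor
razadyne,galantamine,cholinesterase_inhibitor
memantine,memantine,nmda_antagonist
namenda,memantine,nmda_antagonist
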