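,mFG,pFG,aSTG,pSTG,aMTG,pMTG,IFG Oper,IFG Tri,IFG Orb,PMC,pSMG,vATL,lATL
mFG,0,16,61,30,56,18,76,86,83,73,42,49,69
pFG,16,0,76,41,72,26,91,101,99,85,49,64,83
aSTG,61,76,0,42,17,52,37,33,27,46,56,33,31
pSTG,30,41,42,0,46,19,53,64,67,48,20,49,62
aMTG,56,72,17,46,0,50,50,46,32,60,63,18,17
pMTG,18,26,52,19,50,0,70,79,77,67,34,48,64
IFG Oper,76,91,37,53,50,70,0,20,39,17,55,61,64
IFG Tri,86,101,33,64,46,79,20,0,24,36,70,60,55
IFG Orb,83,99,27,67,32,77,39,24,0,55,79,44,35
PMC,73,85,46,48,60,67,17,36,55,0,44,70,75
pSMG,42,49,56,20,63,34,55,70,79,44,0,68,80
vATL,49,64,33,49,18,48,61,60,44,70,68,0,23
lATL,69,83,31,62,17,64,64,55,35,75,80,23,0
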