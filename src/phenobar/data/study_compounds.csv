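compound_id,name,class_code,source,solvent,study_type,stereo_note,tested_concentrations
ARI,Aripiprazole HCl,2,A,DMSO,"E,C",,"1, 3.16, 10, 31.6, 100 (uM)"
BRO,Bromperidol,2,A,DMSO,"E,C",,"0.316, 1, 3.16, 10, 31.6, 100 (uM)"
BUA,(R)-isomer of BUP,1,NA,NA,C,isomer-of:BUP,
BUB,(S)-isomer of BUP,1,NA,NA,C,isomer-of:BUP,
BUP,Bupropion HCl,1,A,water,E,racemic,"10, 31.6, 100, 316, 1000 (uM)"
BUS,Buspirone HCl,3,A,water,"E,C",,"0.316, 1, 3.16, 10, 31.6, 100 (uM)"
CIT,Citalopram HBr,1,A,DMSO,E,racemic,"1, 3.16, 10, 31.6, 100, 316, 1000 (uM)"
CIR,(R)-isomer of CIT,1,NA,NA,C,isomer-of:CIT,
CLO,Clozapine,2,B,DMSO,"E,C",,"0.1, 0.316, 1, 3.16, 10, 31.6, 100 (uM)"
DIA,Diazepam,3,C,DMSO,"E,C",,"1, 3.16, 10, 31.6, 100 (uM)"
DRO,Droperidol,2,A,DMSO,"E,C",,"0.1, 0.316, 1, 3.16, 10, 31.6, 100 (uM)"
DUL,Duloxetine HCl,1,A,DMSO,"E,C",(S)-isomer,"1, 3.16, 10, 31.6, 100 (uM)"
ESC,Escitalopram oxalate,1,A,DMSO,"E,C",isomer-of:CIT,"1, 3.16, 10, 31.6, 100, 316, 1000 (uM)"
FEN,Fenobam,3,A,DMSO,"E,C",,"56.2, 100, 178, 316, 562 (uM)"
FLR,(R)-isomer of FLU,1,NA,NA,C,isomer-of:FLU,
FLS,(S)-isomer of FLU,1,NA,NA,C,isomer-of:FLU,
FLU,Fluoxetine HCl,1,A,DMSO,"E,C",racemic,"1, 3.16, 10, 31.6, 100 (uM)"
HAL,Haloperidol,2,A,DMSO,"E,C",,"1, 3.16, 10, 31.6, 100 (uM)"
IMI,Imipramine HCl,1,A,DMSO,"E,C",,"0.316, 1, 3.16, 10, 31.6 (uM)"
MAL,Maleic acid,4,A,DMSO,"E,C",,"200 (uM)"
MID,Midazolam,3,A,DMSO,"E,C",,"10, 17.8, 31.6, 56.2, 100 (uM)"
OLA,Olanzapine,2,A,DMSO,"E,C",,"0.001, 0.00316, 0.01, 0.0316, 0.1, 0.316, 1, 3.16, 10, 31.6, 100, 316 (uM)"
OXA,Oxalic acid,4,A,DMSO,"E,C",,"100, 316, 1000 (uM)"
PRO,Prochlorperazine dimaleate,2,A,DMSO,"E,C",,"0.316, 1, 3.16, 10, 31.6, 100 (uM)"
SER,Sertraline HCl,1,A,DMSO,"E,C",cis-(1S 4S)-isomer,"1, 3.16, 10, 31.6, 100 (uM)"
SOB,Sodium bromide,4,A,DMSO,E,,"100, 316, 1000 (uM)"
SOC,Sodium chloride,4,A,water,E,,"3.47 (mM)"
TRA,Tracazolate HCl,3,B,DMSO,"E,C",,"1, 3.16, 10, 31.6, 100 (uM)"
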