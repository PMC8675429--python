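sample,age_mean,age_sd,age_lo,age_hi,n,n_male,n_female
ABIDE,17,7.8,6,56,534,439,95
ADHD NF,13,1,12,15,13,7,6
ADNI,76,5.1,60,90,150,70,80
ADNI2GO,73,6.1,56,89,133,55,78
AMC,23,3.4,17,32,92,60,32
Barcelona 1.5T,15,1.8,11,17,30,14,16
Barcelona 3T,15,2.1,11,17,44,24,20
Betula,61,12.9,25,81,234,104,130
BIG 1.5T,28,13.3,13,77,1288,628,660
BIG 3T,24,7.9,18,69,1276,540,736
BIL&GIN,27,7.8,18,57,444,217,227
Bonn,39,6.5,29,50,174,174,0
BRAINSCALE,10,1.4,9,15,270,125,145
BRCATLAS,38,15.8,18,80,153,77,76
CAMH,41,17.6,18,86,128,65,63
Cardiff,25,7.4,18,58,316,87,229
CEG,16,1.7,13,19,32,32,0
CIAM,27,5,19,40,30,16,14
CLING,25,5.3,18,58,320,131,189
CODE,40,13.3,20,64,74,31,43
COMPULS/TS Eurotrain,11,1,9,13,53,36,17
Dublin (1),37,13,17,65,52,23,29
Dublin (2),30,8.3,19,52,92,51,41
Edinburgh,24,2.9,19,31,55,35,20
ENIGMA-HIV,25,4.4,19,33,31,16,15
ENIGMA-OCD (AMC/Huyser),14,2.6,9,17,23,9,14
ENIGMA-OCD (IDIBELL),33,10.1,18,61,65,29,36
ENIGMA-OCD (Kyushu/Nakao),39,12.5,22,63,40,15,25
ENIGMA-OCD (London Cohort/Mataix-Cols),37,11.2,21,63,32,11,21
ENIGMA-OCD (van den Heuvel 1.5T),31,7.6,21,53,48,18,30
ENIGMA-OCD (van den Heuvel 3T),39,11.2,22,64,35,16,19
ENIGMA-OCD-3T-CONTROLS,31,10.6,19,56,27,10,17
FBIRN,37,11.2,19,60,173,123,50
FIDMAG,38,10.2,19,64,122,53,69
GSP,26,14.9,18,89,1962,860,1102
HMS,40,12.2,19,64,55,21,34
HUBIN,42,8.9,19,56,99,66,33
IDIVAL (1),65,10.2,49,87,31,10,21
IDIVAL (3),30,7.7,19,50,114,69,45
IDIVAL(2),28,7.6,15,52,79,49,30
IMAGEN,14,0.4,13,16,1744,864,880
IMH,32,10,20,59,79,50,29
IMpACT-NL,37,12,19,63,134,52,82
Indiana 1.5T,60,11,37,79,41,7,34
Indiana 3T,27,18.8,6,73,197,95,102
Johns Hopkins,44,12.5,20,65,87,41,46
KaSP,27,5.7,20,43,32,15,17
Leiden,17,4.8,8,29,565,274,291
MAS,78,4.5,70,89,361,137,224
MCIC,33,12,18,60,93,63,30
Melbourne,20,3,15,26,102,54,48
METHCT,27,7.3,18,53,62,48,14
MHRC,22,2.9,16,28,52,52,0
Moods,33,9.8,18,51,310,146,164
NCNG,50,16.7,19,79,311,92,219
NESDA,40,9.8,21,56,65,22,43
NeuroIMAGE,17,3.7,8,29,376,172,204
Neuroventure,14,0.6,12,15,137,62,75
NTR (1),15,1.4,11,18,34,11,23
NTR (2),34,10.3,19,57,105,39,66
NTR (3),30,5.9,20,42,29,11,18
NU,41,18.8,17,68,15,1,14
NUIG,37,11.5,18,58,89,50,39
NYU,31,8.7,19,52,51,31,20
OATS (1),71,5.3,65,84,94,27,67
OATS (2),68,4.4,65,81,33,13,20
OATS (3),69,4.3,65,81,128,44,84
OATS (4),70,4.6,65,89,95,23,72
OLIN,36,12.8,21,87,594,236,358
Oxford,16,1.4,14,19,38,18,20
PING,12,4.9,3,21,518,271,247
QTIM,23,3.4,16,30,342,112,230
Sao Paolo 1,27,5.8,17,43,69,45,24
Sao Paolo 3,30,8.1,18,50,83,44,39
SCORE,25,4.3,19,39,44,17,27
SHIP 2,55,12.3,31,84,368,206,162
SHIP TREND,50,13.9,21,81,788,439,349
StagedDep,47,8,27,59,84,20,64
Stanford,37,10.7,19,61,54,20,34
STROKEMRI,42,21.3,18,77,47,17,30
Sydney,37,21.1,12,79,147,58,89
TOP,35,9.8,18,73,296,155,141
Tuebingen,40,12.1,24,61,53,24,29
UMC Utrecht 1.5T,32,12.1,17,66,289,171,118
UMCU 3T,45,15.2,19,81,109,52,57
UNIBA,27,8.7,18,63,130,66,64
UPENN,36,13.6,16,85,185,85,100
Yale,14,2.2,10,18,23,12,11
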