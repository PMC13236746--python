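study_id,date,n_subjects,SCR,PSR,RAR,HPR
SC4B,2017-10,8,0.75,1.08,0.22,0.77
PubFe,2018-03,12,0.44,0.93,0.35,0.74
VC7B,2018-04,17,0.77,0.66,.,.
DoxMemP,2018-07,20,0.81,.,0.55,1.26
FR,2018-07,22,0.74,.,0.52,1.00
TC,2018-07,19,0.70,.,0.55,1.20
FSS6B,2020-01,17,0.44,0.49,.,.
FER02,2020-03,68,0.40,0.52,0.28,0.26
FER01,2021-11,26,0.40,0.37,.,0.74
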