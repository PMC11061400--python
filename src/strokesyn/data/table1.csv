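patient,age,sex,lesion_side,type,days_after_stroke,fmul,fmarm,bs
01,69,Male,Right,Ischemic,143,65,41,V
02,76,Female,Right,Ischemic,150,46,28,III
03,64,Male,Right,Hemorrhagic,121,66,42,V
04,36,Male,Left,Ischemic,26,41,30,IV
05,33,Male,Left,Ischemic,36,46,30,IV
06,32,Male,Right,Hemorrhagic,181,29,21,III
07,72,Male,Right,Hemorrhagic,126,16,13,II
08,36,Female,Right,Ischemic,52,26,16,III
09,86,Male,Right,Hemorrhagic,36,49,29,IV
10,65,Male,Right,Hemorrhagic,573,27,13,III
11,30,Male,Left,Hemorrhagic,197,17,15,III
12,73,Female,Right,Ischemic,12,65,41,VI
13,60,Male,Left,Ischemic,32,64,40,V
14,52,Male,Left,Hemorrhagic,12,34,18,IV
15,60,Female,Left,Ischemic,43,29,23,III
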