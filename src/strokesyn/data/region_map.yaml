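# Default stand-in montage: 3 regions x 2 hemispheres x 4 channels.
# Channel i on the left mirrors channel i+12 on the right.
1: {region: PMC, hemisphere: left, mirror: 13}
2: {region: PMC, hemisphere: left, mirror: 14}
3: {region: PMC, hemisphere: left, mirror: 15}
4: {region: PMC, hemisphere: left, mirror: 16}
5: {region: M1, hemisphere: left, mirror: 17}
6: {region: M1, hemisphere: left, mirror: 18}
7: {region: M1, hemisphere: left, mirror: 19}
8: {region: M1, hemisphere: left, mirror: 20}
9: {region: S1, hemisphere: left, mirror: 21}
10: {region: S1, hemisphere: left, mirror: 22}
11: {region: S1, hemisphere: left, mirror: 23}
12: {region: S1, hemisphere: left, mirror: 24}
13: {region: PMC, hemisphere: right, mirror: 1}
14: {region: PMC, hemisphere: right, mirror: 2}
15: {region: PMC, hemisphere: right, mirror: 3}
16: {region: PMC, hemisphere: right, mirror: 4}
17: {region: M1, hemisphere: right, mirror: 5}
18: {region: M1, hemisphere: right, mirror: 6}
19: {region: M1, hemisphere: right, mirror: 7}
20: {region: M1, hemisphere: right, mirror: 8}
21: {region: S1, hemisphere: right, mirror: 9}
22: {region: S1, hemisphere: right, mirror: 10}
23: {region: S1, hemisphere: right, mirror: 11}
24: {region: S1, hemisphere: right, mirror: 12}
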