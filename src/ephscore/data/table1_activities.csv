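ligand_id,label,pic50
2,Gly,4.31
4,l-Ala,4.70
5,d-Ala,4.51
6,l-Val,4.62
7,d-Val,4.76
8,l-Ser,4.48
9,d-Ser,4.22
14,l-Met,4.56
15,d-Met,4.56
16,l-Phe,5.18
17,d-Phe,5.12
18,l-Tyr,4.30
19,d-Tyr,4.00
20,l-Trp,5.69
21,d-Trp,4.69
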