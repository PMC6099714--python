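ligand_id,residue_group,eel_mtp,eel_pen,eex,edel,ecorr,edas
20,total,-89.2,-12.1,34.8,-17.0,-19.2,-28.8
16,total,-90.7,-11.8,36.9,-20.5,-14.4,-24.6
17,total,-98.5,-12.9,41.3,-22.5,-17.0,-28.5
7,total,-75.2,-8.1,17.6,-11.7,-10.3,-16.1
4,total,-97.1,-11.4,34.8,-20.4,-9.4,-19.4
21,total,-72.8,-9.5,24.4,-13.0,-19.9,-26.6
6,total,-99.3,-10.7,38.1,-22.5,-10.0,-21.1
14,total,-89.9,-11.2,32.0,-18.6,-13.0,-22.4
15,total,-80.5,-9.0,22.2,-13.3,-13.6,-21.0
5,total,-75.1,-7.1,15.5,-10.2,-8.7,-13.8
8,total,-85.9,-10.7,26.2,-15.8,-9.3,-17.8
2,total,-64.6,-4.7,13.1,-8.8,-7.5,-11.1
18,total,-65.9,-7.3,17.9,-10.0,-14.1,-19.4
9,total,-69.0,-5.7,12.1,-8.8,-9.7,-14.2
19,total,-65.3,-8.8,18.3,-10.7,-15.4,-20.4
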