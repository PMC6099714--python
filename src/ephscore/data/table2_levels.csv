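ligand_id,eel_mtp10,eel10,e10,escf,emp2,eelmtp_plus_edas
20,-89.2,-101.3,-66.5,-83.5,-102.7,-118.0
16,-90.7,-102.5,-65.6,-86.1,-100.5,-115.3
17,-98.5,-111.4,-70.1,-92.6,-109.6,-127.0
7,-75.2,-83.3,-65.7,-77.4,-87.7,-91.3
4,-97.1,-108.5,-73.7,-94.1,-103.5,-116.5
21,-72.8,-82.3,-57.9,-70.9,-90.8,-99.4
6,-99.3,-110.0,-71.9,-94.4,-104.4,-120.4
14,-89.9,-101.1,-69.1,-87.7,-100.7,-112.3
15,-80.5,-89.5,-67.3,-80.6,-94.2,-101.5
5,-75.1,-82.2,-66.7,-76.9,-85.6,-88.9
8,-85.9,-96.6,-70.4,-86.2,-95.5,-103.7
2,-64.6,-69.3,-56.2,-65.0,-72.5,-75.7
18,-65.9,-73.2,-55.3,-65.3,-79.4,-85.3
9,-69.0,-74.7,-62.6,-71.4,-81.1,-83.2
19,-65.3,-74.1,-55.8,-66.5,-81.9,-85.7
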