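ligand_id,dg_solv,dg_solv_el,dg_solv_nonel
20,-73.6,-81.2,7.6
16,-66.4,-73.5,7.2
17,-67.9,-75.3,7.4
7,-63.2,-70.0,6.8
4,-70.9,-77.0,6.0
21,-67.5,-75.2,7.7
6,-68.6,-75.5,7.0
14,-69.0,-75.9,6.9
15,-66.3,-73.5,7.2
5,-67.2,-73.4,6.2
8,-66.2,-72.0,5.8
2,-62.8,-68.1,5.3
18,-71.7,-78.9,7.2
9,-64.2,-70.2,6.0
19,-67.2,-74.9,7.7
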