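system,r_mp2,r_eelmtp_plus_edas,sd_dgsolv
EphA2-ephrinA1,-0.69,-0.72,3.0
menin-MLL,-0.55,-0.87,2.5
FAAH,-0.83,-0.67,1.5
TbPTR1,-0.89,-0.96,1.1
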