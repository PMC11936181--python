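compound_id,molecular_weight,logp,hbd_count,hba_count
Corilagin,634.5,0.1,11,18
Apigetrin,432.4,-0.1,6,10
Protopine,353.4,2.8,0,6
5-methoxyflavone,252.26,3.5,0,3
"7,3',4'-trihydroxyisoflavone",270.24,2.1,3,5
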