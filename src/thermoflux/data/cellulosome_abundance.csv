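protein_id,cellulose_batch,cellobiose_batch,switchgrass
CipA,1.0,1.0,1.0
CelS,2.31,2.812,0.722
CelK,1.447,2.059,1.857
CbhA,2.944,0.843,0.666
XynC,1.325,2.212,0.752
OlpB,2.038,2.445,1.368
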