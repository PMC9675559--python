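gene	weight
CCL5	0.124
CD27	0.072
CD274	0.042
CD276	0.083
CD8A	0.031
CMKLR1	0.151
CXCL9	0.074
CXCR6	0.004
HLA-DQA1	0.020
HLA-DRB1	0.058
HLA-E	0.075
IDO1	0.060
LAG3	0.123
NKG7	0.075
PDCD1LG2	0.003
PSMB10	0.032
STAT1	0.250
TIGIT	0.084
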