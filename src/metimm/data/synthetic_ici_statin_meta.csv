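study_id,hr,ci_lower,ci_upper,n,subgroup
PanCancer-A,0.78,0.61,0.99,312,immunotherapy
PanCancer-B,0.69,0.48,0.98,247,immunotherapy
PanCancer-C,0.84,0.70,1.01,510,immunotherapy
PanCancer-D,0.62,0.43,0.90,386,immunotherapy
PanCancer-E,0.91,0.72,1.15,428,immunotherapy
PanCancer-F,0.74,0.52,1.05,252,immunotherapy
InHouse,0.55,0.31,0.97,101,immunotherapy
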