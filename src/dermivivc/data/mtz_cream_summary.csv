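product_id,run_label,arc,auc
reference,run1,37.80,77.46
T1,run1,32.89,77.62
reference,run2,38.47,77.46
T2,run2,27.42,60.98
T3,run2,51.20,96.78
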