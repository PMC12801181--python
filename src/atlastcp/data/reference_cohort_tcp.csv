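patient_id,risk_group,method1,method2,method3,method4
1,High,93.6,92.9,99.6,86.6
2,Intermediate,95.9,95.8,99.9,92.3
3,Intermediate,96.5,97.1,99.9,94.9
4,Intermediate,96.1,91.4,99.5,85.1
5,High,92.9,93.5,99.7,86.7
6,Intermediate,90.7,94.1,99.6,89.1
7,Intermediate,91.2,92.8,99.5,87.9
8,Intermediate,86.1,81.6,92.4,71.8
9,Intermediate,89.1,86.7,96.4,76.7
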