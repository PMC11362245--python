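trial_id,x,y,z,deviation
1,53.81,87.90,-1007.23,3.0182
2,54.94,92.89,-1006.66,3.4664
3,55.97,91.51,-1007.51,1.9343
4,54.22,90.32,-1007.28,1.7857
5,53.84,89.81,-1006.06,3.0052
6,53.72,91.41,-1005.85,3.4976
7,55.04,91.03,-1005.63,3.1801
8,56.71,90.03,-1007.64,1.7028
9,54.41,92.65,-1005.47,4.1931
10,55.70,93.18,-1004.92,4.8634
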