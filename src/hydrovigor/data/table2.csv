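lot_id,theta_H_MPah,psi_b50_MPa,sigma_phib,r2
1,14.171,-0.335,0.309,0.885
2,14.770,-0.278,0.276,0.906
3,13.606,-0.485,0.283,0.876
4,10.086,-0.377,0.270,0.844
5,11.819,-0.443,0.286,0.917
6,8.897,-0.441,0.305,0.783
7,13.618,-0.479,0.319,0.859
8,14.114,-0.450,0.291,0.847
9,13.763,-0.475,0.322,0.838
10,12.814,-0.398,0.267,0.866
11,13.636,-0.489,0.333,0.879
12,8.799,-0.522,0.299,0.833
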