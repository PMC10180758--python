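lot_id,psi_mpa,germination_pct
1,0.0,90.0
1,-0.2,58.9
1,-0.4,36.7
1,-0.6,31.1
1,-0.8,0.0
2,0.0,85.6
2,-0.2,51.1
2,-0.4,28.9
2,-0.6,17.8
2,-0.8,0.0
3,0.0,96.7
3,-0.2,87.8
3,-0.4,57.8
3,-0.6,48.9
3,-0.8,1.1
4,0.0,93.3
4,-0.2,62.2
4,-0.4,48.9
4,-0.6,35.6
4,-0.8,1.1
5,0.0,91.1
5,-0.2,81.1
5,-0.4,47.8
5,-0.6,38.9
5,-0.8,0.0
6,0.0,92.2
6,-0.2,81.1
6,-0.4,55.6
6,-0.6,51.1
6,-0.8,3.3
7,0.0,88.9
7,-0.2,86.7
7,-0.4,52.2
7,-0.6,45.6
7,-0.8,3.3
8,0.0,93.3
8,-0.2,76.7
8,-0.4,50.0
8,-0.6,44.4
8,-0.8,0.0
9,0.0,90.0
9,-0.2,77.8
9,-0.4,58.9
9,-0.6,51.1
9,-0.8,6.7
10,0.0,93.3
10,-0.2,68.9
10,-0.4,43.3
10,-0.6,37.8
10,-0.8,0.0
11,0.0,90.0
11,-0.2,82.2
11,-0.4,60.0
11,-0.6,45.6
11,-0.8,2.2
12,0.0,95.6
12,-0.2,91.1
12,-0.4,68.9
12,-0.6,56.7
12,-0.8,6.7
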