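lot_id,condition,emergence_pct,sdw_mg,svi
1,control,66.7,49.9,3280.1
1,water_stress,35.6,26.1,924.5
1,salinity_stress,38.9,28.4,1088.3
1,deep_sowing,28.9,15.3,432.3
1,cold_stress,41.1,22.7,924.9
2,control,54.4,39.7,2153.4
2,water_stress,28.9,15.4,433.5
2,salinity_stress,26.7,24.1,631.2
2,deep_sowing,15.6,9.0,135.2
2,cold_stress,32.2,17.7,561.1
3,control,77.8,53.9,4175.9
3,water_stress,43.3,34.6,1484.9
3,salinity_stress,41.1,30.9,1262.6
3,deep_sowing,33.3,22.1,729.4
3,cold_stress,44.4,25.0,1099.1
4,control,73.3,45.3,3306.8
4,water_stress,41.1,20.7,849.4
4,salinity_stress,44.4,26.3,1173.8
4,deep_sowing,31.1,14.7,453.2
4,cold_stress,48.9,22.0,1079.3
5,control,77.8,43.4,3360.9
5,water_stress,45.6,23.2,1045.5
5,salinity_stress,43.3,33.7,1465.6
5,deep_sowing,32.2,12.9,408.3
5,cold_stress,50.0,27.0,1350.1
6,control,80.0,50.2,4029.1
6,water_stress,44.4,29.9,1324.0
6,salinity_stress,46.7,27.3,1262.0
6,deep_sowing,38.9,21.9,844.7
6,cold_stress,54.4,22.0,1194.5
7,control,74.4,56.9,4213.2
7,water_stress,47.8,32.5,1540.0
7,salinity_stress,51.1,40.8,2093.2
7,deep_sowing,40.0,25.2,1008.3
7,cold_stress,53.3,29.5,1538.2
8,control,72.2,42.4,3048.9
8,water_stress,41.1,26.4,1081.2
8,salinity_stress,42.2,35.6,1497.3
8,deep_sowing,32.2,16.1,508.7
8,cold_stress,52.2,27.3,1425.7
9,control,81.1,47.3,3846.3
9,water_stress,37.8,23.1,869.3
9,salinity_stress,38.9,37.2,1434.6
9,deep_sowing,26.7,13.1,346.5
9,cold_stress,43.3,21.7,927.8
10,control,66.7,42.8,2848.3
10,water_stress,35.6,23.9,848.0
10,salinity_stress,34.4,26.8,919.6
10,deep_sowing,25.6,16.2,396.8
10,cold_stress,43.3,20.4,886.1
11,control,78.9,50.2,3943.0
11,water_stress,46.7,32.9,1533.1
11,salinity_stress,48.9,39.2,1912.9
11,deep_sowing,41.1,24.7,1011.0
11,cold_stress,52.2,28.3,1471.9
12,control,83.3,55.6,4629.4
12,water_stress,52.2,36.8,1906.0
12,salinity_stress,53.3,42.2,2241.6
12,deep_sowing,43.3,25.6,1108.4
12,cold_stress,57.8,39.0,2235.9
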