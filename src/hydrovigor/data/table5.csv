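lot_id,production_year,storage_years,seed_moisture_pct,thousand_seed_weight_g,hard_seed_pct
1,2018,4,8.76,3.359,2.2
2,2016,6,8.52,3.392,2.2
3,2017,5,8.69,3.383,0.0
4,2017,5,8.61,3.389,1.1
5,2019,3,8.69,3.501,2.2
6,2018,4,8.48,3.384,1.1
7,2018,4,8.57,3.462,4.4
8,2019,3,8.86,3.431,2.2
9,2019,3,8.88,3.480,2.2
10,2017,5,8.72,3.427,0.0
11,2021,1,9.10,3.390,3.3
12,2021,1,8.93,3.415,2.2
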