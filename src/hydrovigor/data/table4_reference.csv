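parameter,condition,variable,r_printed,p_printed
theta_H,germination_test,germination_pct,-0.463,
psi_b50,germination_test,germination_pct,-0.972,<0.001
sigma_phib,germination_test,germination_pct,0.424,
theta_H,control,emergence_pct,-0.531,
psi_b50,control,emergence_pct,-0.900,<0.001
sigma_phib,control,emergence_pct,0.476,
theta_H,control,sdw_mg,-0.268,
psi_b50,control,sdw_mg,-0.642,0.024
sigma_phib,control,sdw_mg,0.546,
theta_H,control,svi,-0.458,
psi_b50,control,svi,-0.858,<0.001
sigma_phib,control,svi,0.563,
theta_H,water_stress,emergence_pct,-0.557,
psi_b50,water_stress,emergence_pct,-0.853,<0.001
sigma_phib,water_stress,emergence_pct,0.391,
theta_H,water_stress,sdw_mg,-0.290,
psi_b50,water_stress,sdw_mg,-0.807,0.002
sigma_phib,water_stress,sdw_mg,0.476,
theta_H,water_stress,svi,-0.415,
psi_b50,water_stress,svi,-0.845,0.001
sigma_phib,water_stress,svi,0.462,
theta_H,salinity_stress,emergence_pct,-0.552,
psi_b50,salinity_stress,emergence_pct,-0.780,0.003
sigma_phib,salinity_stress,emergence_pct,0.504,
theta_H,salinity_stress,sdw_mg,-0.031,
psi_b50,salinity_stress,sdw_mg,-0.820,0.001
sigma_phib,salinity_stress,sdw_mg,0.666,0.018
theta_H,salinity_stress,svi,-0.284,
psi_b50,salinity_stress,svi,-0.834,0.001
sigma_phib,salinity_stress,svi,0.616,0.033
theta_H,deep_sowing,emergence_pct,-0.523,
psi_b50,deep_sowing,emergence_pct,-0.803,0.002
sigma_phib,deep_sowing,emergence_pct,0.518,
theta_H,deep_sowing,sdw_mg,-0.347,
psi_b50,deep_sowing,sdw_mg,-0.742,0.006
sigma_phib,deep_sowing,sdw_mg,0.485,
theta_H,deep_sowing,svi,-0.423,
psi_b50,deep_sowing,svi,-0.754,0.005
sigma_phib,deep_sowing,svi,0.529,
theta_H,cold_stress,emergence_pct,-0.630,0.028
psi_b50,cold_stress,emergence_pct,-0.776,0.003
sigma_phib,cold_stress,emergence_pct,0.351,
theta_H,cold_stress,sdw_mg,-0.375,
psi_b50,cold_stress,sdw_mg,-0.734,0.007
sigma_phib,cold_stress,sdw_mg,0.341,
theta_H,cold_stress,svi,-0.508,
psi_b50,cold_stress,svi,-0.763,0.004
sigma_phib,cold_stress,svi,0.335,
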