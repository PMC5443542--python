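goal,subgoal,score,status,future,trend,pressure,resilience
Food Provision,,64.28,58.66,69.90,0.02,,
Food Provision,FIS,59.36,54.00,64.72,0.02,16.69,72.81
Food Provision,MAR,92.88,85.77,100.00,0.04,14.01,68.68
Aboriginal Needs,,35.42,32.39,38.45,-0.02,13.58,73.66
Natural Products,,44.02,41.90,46.13,-0.16,13.81,76.43
Carbon Storage,,61.64,57.28,66.00,-0.01,16.52,64.06
Coastal Protection,,95.89,91.79,100.00,-0.01,23.81,64.06
Coastal Livelihoods,,89.87,86.74,93.00,0.03,,
Coastal Livelihoods,LIV,79.74,73.48,86.00,0.03,14.89,60.08
Coastal Livelihoods,ECO,100.00,100.00,100.00,0.02,14.87,73.55
Tourism & Recreation,,25.19,23.93,26.45,0.00,30.64,62.97
Iconic Places & Species,,84.91,80.00,89.81,-0.10,16.99,74.46
Iconic Places & Species,LSP,33.89,25.27,42.52,0.78,22.84,72.06
Iconic Places & Species,SP,59.40,52.63,66.17,0.34,,
Clean Waters,,78.70,84.31,73.09,-0.32,38.19,62.97
Biodiversity,,91.05,84.83,97.28,-0.04,,
Biodiversity,HAB,92.72,85.43,100.00,0.00,14.73,75.38
Biodiversity,SPP,89.39,84.22,94.55,-0.08,19.67,72.83
OVERALL,,64.55,,67.65,,,
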