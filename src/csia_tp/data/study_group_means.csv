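species,tissue,n,aa,mean_d15n,sd_d15n
bowhead_whale,baleen,2,Glx,18.75,
bowhead_whale,baleen,2,Asx,13.26,
bowhead_whale,baleen,2,Ala,16.11,
bowhead_whale,baleen,2,Ile,20.95,
bowhead_whale,baleen,2,Leu,15.86,
bowhead_whale,baleen,2,Pro,20.70,
bowhead_whale,baleen,2,Val,19.39,
bowhead_whale,baleen,2,Gly,9.36,
bowhead_whale,baleen,2,Phe,6.17,
bowhead_whale,skin,10,Glx,19.02,0.9
bowhead_whale,skin,10,Asx,13.91,0.7
bowhead_whale,skin,10,Ala,17.03,0.8
bowhead_whale,skin,10,Ile,17.42,0.7
bowhead_whale,skin,10,Leu,15.24,0.9
bowhead_whale,skin,10,Pro,19.41,0.7
bowhead_whale,skin,10,Val,19.29,0.8
bowhead_whale,skin,10,Gly,8.18,0.8
bowhead_whale,skin,10,Phe,5.53,0.9
beluga,skin,4,Glx,28.99,1.4
beluga,skin,4,Asx,22.45,1.4
beluga,skin,4,Ala,26.77,0.8
beluga,skin,4,Ile,27.95,0.8
beluga,skin,4,Leu,27.65,0.9
beluga,skin,4,Pro,32.37,1.2
beluga,skin,4,Val,29.55,0.9
beluga,skin,4,Gly,3.73,2.2
beluga,skin,4,Phe,9.14,1.3
beluga,dentine_collagen,9,Glx,28.49,1.0
beluga,dentine_collagen,9,Asx,22.84,0.9
beluga,dentine_collagen,9,Ala,29.07,0.5
beluga,dentine_collagen,9,Ile,28.75,1.1
beluga,dentine_collagen,9,Leu,27.89,1.3
beluga,dentine_collagen,9,Pro,29.30,0.8
beluga,dentine_collagen,9,Val,31.25,0.8
beluga,dentine_collagen,9,Gly,14.64,1.0
beluga,dentine_collagen,9,Phe,10.04,1.0
common_dolphin,skin,9,Glx,23.62,3.8
common_dolphin,skin,9,Asx,19.35,2.0
common_dolphin,skin,9,Ala,22.30,2.3
common_dolphin,skin,9,Ile,22.47,2.1
common_dolphin,skin,9,Leu,24.25,1.8
common_dolphin,skin,9,Pro,25.67,2.2
common_dolphin,skin,9,Val,26.72,2.5
common_dolphin,skin,9,Gly,0.84,2.6
common_dolphin,skin,9,Phe,9.97,2.1
fe_killer_whale,dentine_collagen,3,Glx,29.69,0.4
fe_killer_whale,dentine_collagen,3,Asx,24.00,0.6
fe_killer_whale,dentine_collagen,3,Ala,27.99,0.6
fe_killer_whale,dentine_collagen,3,Ile,28.90,0.5
fe_killer_whale,dentine_collagen,3,Leu,29.30,0.8
fe_killer_whale,dentine_collagen,3,Pro,28.24,0.5
fe_killer_whale,dentine_collagen,3,Val,32.04,0.9
fe_killer_whale,dentine_collagen,3,Gly,10.52,0.5
fe_killer_whale,dentine_collagen,3,Phe,10.48,0.4
sperm_whale,skin,13,Glx,25.81,2.2
sperm_whale,skin,13,Asx,22.29,2.0
sperm_whale,skin,13,Ala,24.13,2.7
sperm_whale,skin,13,Ile,25.39,2.5
sperm_whale,skin,13,Leu,25.25,2.1
sperm_whale,skin,13,Pro,26.04,1.5
sperm_whale,skin,13,Val,25.46,3.5
sperm_whale,skin,13,Gly,11.93,3.5
sperm_whale,skin,13,Phe,10.74,1.5
sperm_whale,dentine_collagen,6,Glx,23.33,1.1
sperm_whale,dentine_collagen,6,Asx,18.13,0.6
sperm_whale,dentine_collagen,6,Ala,24.25,1.0
sperm_whale,dentine_collagen,6,Ile,25.28,0.6
sperm_whale,dentine_collagen,6,Leu,25.28,0.7
sperm_whale,dentine_collagen,6,Pro,21.80,0.6
sperm_whale,dentine_collagen,6,Val,26.92,0.4
sperm_whale,dentine_collagen,6,Gly,9.48,1.0
sperm_whale,dentine_collagen,6,Phe,7.82,1.1
mme_killer_whale,dentine_collagen,4,Glx,27.77,1.3
mme_killer_whale,dentine_collagen,4,Asx,24.03,2.0
mme_killer_whale,dentine_collagen,4,Ala,26.69,1.6
mme_killer_whale,dentine_collagen,4,Ile,27.58,2.4
mme_killer_whale,dentine_collagen,4,Leu,27.23,1.9
mme_killer_whale,dentine_collagen,4,Pro,28.89,1.6
mme_killer_whale,dentine_collagen,4,Val,28.88,1.2
mme_killer_whale,dentine_collagen,4,Gly,13.31,2.8
mme_killer_whale,dentine_collagen,4,Phe,14.31,1.7
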