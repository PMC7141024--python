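specimen_id,species,tissue,d15n_glx_phe,tp_sc,tp1,tp1_sd,tp2,tp2_sd,tp3,tp3_sd,tp4,tp4_sd
bw-ba-01,bowhead_whale,baleen,12.40,3.2,2.2,0.3,1.9,0.3,2.6,0.3,2.4,0.6
bw-ba-02,bowhead_whale,baleen,12.75,3.2,2.2,0.3,1.9,0.3,2.7,0.3,2.5,0.6
bw-sk-01,bowhead_whale,skin,14.47,3.2,2.5,0.3,1.9,0.2,2.9,0.3,3.0,0.5
bw-sk-02,bowhead_whale,skin,12.63,3.2,2.2,0.2,1.9,0.2,2.6,0.2,2.5,0.5
bw-sk-03,bowhead_whale,skin,12.68,3.2,2.2,0.2,1.9,0.3,2.7,0.2,2.5,0.5
bw-sk-04,bowhead_whale,skin,13.57,3.2,2.3,0.3,1.9,0.2,2.8,0.2,2.7,0.5
bw-sk-05,bowhead_whale,skin,13.82,3.2,2.4,0.3,2.0,0.2,2.8,0.3,2.8,0.5
bw-sk-06,bowhead_whale,skin,13.28,3.2,2.3,0.3,2.0,0.2,2.7,0.2,2.7,0.5
bw-sk-07,bowhead_whale,skin,13.31,3.2,2.3,0.3,1.9,0.2,2.7,0.2,2.7,0.5
bw-sk-08,bowhead_whale,skin,13.84,3.2,2.4,0.3,2.0,0.2,2.8,0.3,2.8,0.5
bw-sk-09,bowhead_whale,skin,14.49,3.2,2.5,0.3,1.9,0.2,2.9,0.3,3.0,0.5
bw-sk-10,bowhead_whale,skin,13.84,3.2,2.4,0.3,2.0,0.3,2.8,0.3,2.8,0.5
dl-sk-01,beluga,skin,20.16,4.0,3.2,0.4,3.2,0.4,3.6,0.3,4.6,0.6
dl-sk-02,beluga,skin,19.46,4.0,3.1,0.4,3.5,0.4,3.6,0.3,4.4,0.5
dl-sk-03,beluga,skin,19.76,4.0,3.2,0.4,3.4,0.4,3.6,0.3,4.5,0.6
dl-sk-04,beluga,skin,20.01,4.0,3.2,0.4,3.4,0.4,3.6,0.3,4.6,0.6
dl-dc-01,beluga,dentine_collagen,17.10,4.0,2.8,0.3,2.6,0.3,3.2,0.3,3.7,0.5
dl-dc-02,beluga,dentine_collagen,18.64,4.0,3.0,0.4,2.7,0.3,3.4,0.3,4.2,0.5
dl-dc-03,beluga,dentine_collagen,18.17,4.0,2.9,0.3,2.7,0.3,3.4,0.3,4.1,0.5
dl-dc-04,beluga,dentine_collagen,18.97,4.0,3.0,0.4,2.5,0.3,3.5,0.3,4.3,0.6
dl-dc-05,beluga,dentine_collagen,20.73,4.0,3.3,0.4,2.7,0.3,3.7,0.4,4.8,0.6
dl-dc-06,beluga,dentine_collagen,16.91,4.0,2.8,0.3,2.6,0.3,3.2,0.3,3.7,0.5
dl-dc-07,beluga,dentine_collagen,18.88,4.0,3.0,0.4,2.7,0.3,3.5,0.3,4.3,0.5
dl-dc-08,beluga,dentine_collagen,18.54,4.0,3.0,0.4,2.6,0.3,3.4,0.3,4.2,0.5
dl-dc-09,beluga,dentine_collagen,18.14,4.0,2.9,0.3,2.7,0.3,3.4,0.3,4.0,0.5
cd-sk-01,common_dolphin,skin,11.20,4.2,2.0,0.2,3.1,0.4,2.5,0.2,2.1,0.5
cd-sk-02,common_dolphin,skin,13.87,4.2,2.4,0.3,2.8,0.3,2.8,0.3,2.8,0.5
cd-sk-03,common_dolphin,skin,11.28,4.2,2.0,0.2,3.1,0.4,2.5,0.2,2.1,0.5
cd-sk-04,common_dolphin,skin,9.23,4.2,1.8,0.2,2.8,0.3,2.2,0.2,1.5,0.5
cd-sk-05,common_dolphin,skin,13.22,4.2,2.3,0.3,3.0,0.3,2.7,0.2,2.6,0.5
cd-sk-06,common_dolphin,skin,17.55,4.2,2.9,0.3,3.0,0.3,3.3,0.3,3.9,0.5
cd-sk-07,common_dolphin,skin,11.24,4.2,2.0,0.2,2.7,0.3,2.5,0.2,2.1,0.5
cd-sk-08,common_dolphin,skin,18.02,4.2,2.9,0.3,3.0,0.4,3.4,0.3,4.0,0.5
cd-sk-09,common_dolphin,skin,17.22,4.2,2.8,0.3,2.9,0.3,3.3,0.3,3.8,0.5
fe-dc-01,fe_killer_whale,dentine_collagen,19.50,4.3,3.1,0.4,2.9,0.3,3.6,0.3,4.4,0.6
fe-dc-02,fe_killer_whale,dentine_collagen,18.71,4.3,3.0,0.4,2.9,0.3,3.5,0.3,4.2,0.5
fe-dc-03,fe_killer_whale,dentine_collagen,19.40,4.3,3.1,0.4,2.9,0.3,3.5,0.3,4.4,0.6
pm-sk-01,sperm_whale,skin,15.16,4.4,2.6,0.3,2.2,0.2,3.0,0.3,3.2,0.5
pm-sk-02,sperm_whale,skin,16.36,4.4,2.7,0.3,2.2,0.2,3.1,0.3,3.5,0.5
pm-sk-03,sperm_whale,skin,15.27,4.4,2.6,0.3,2.2,0.2,3.0,0.3,3.2,0.5
pm-sk-04,sperm_whale,skin,17.73,4.4,2.9,0.3,2.6,0.3,3.3,0.3,3.9,0.5
pm-sk-05,sperm_whale,skin,14.97,4.4,2.5,0.3,2.0,0.2,3.0,0.3,3.1,0.5
pm-sk-06,sperm_whale,skin,15.15,4.4,2.6,0.3,2.3,0.3,3.0,0.3,3.2,0.5
pm-sk-07,sperm_whale,skin,14.99,4.4,2.5,0.3,2.0,0.2,3.0,0.3,3.1,0.5
pm-sk-08,sperm_whale,skin,11.95,4.4,2.1,0.2,1.6,0.2,2.6,0.2,2.3,0.5
pm-sk-09,sperm_whale,skin,12.64,4.4,2.2,0.2,1.9,0.2,2.7,0.2,2.5,0.5
pm-sk-10,sperm_whale,skin,18.57,4.4,3.0,0.3,3.0,0.4,3.4,0.3,4.2,0.5
pm-sk-11,sperm_whale,skin,13.62,4.4,2.3,0.3,2.0,0.2,2.8,0.3,2.8,0.5
pm-sk-12,sperm_whale,skin,16.67,4.4,2.8,0.3,2.5,0.3,3.2,0.3,3.6,0.5
pm-sk-13,sperm_whale,skin,12.84,4.4,2.2,0.3,2.1,0.2,2.7,0.2,2.5,0.5
pm-dc-01,sperm_whale,dentine_collagen,15.30,4.4,2.6,0.3,2.6,0.3,3.0,0.3,3.2,0.5
pm-dc-02,sperm_whale,dentine_collagen,15.80,4.4,2.6,0.3,2.6,0.3,3.1,0.3,3.4,0.5
pm-dc-03,sperm_whale,dentine_collagen,16.10,4.4,2.7,0.3,2.5,0.3,3.1,0.3,3.5,0.5
pm-dc-04,sperm_whale,dentine_collagen,13.60,4.4,2.3,0.3,2.5,0.3,2.8,0.3,2.7,0.5
pm-dc-05,sperm_whale,dentine_collagen,17.10,4.4,2.8,0.3,2.5,0.3,3.2,0.3,3.7,0.5
pm-dc-06,sperm_whale,dentine_collagen,15.20,4.4,2.6,0.3,2.4,0.3,3.0,0.3,3.2,0.5
mm-dc-01,mme_killer_whale,dentine_collagen,13.36,5.0,2.3,0.3,2.2,0.2,2.7,0.3,2.7,0.5
mm-dc-02,mme_killer_whale,dentine_collagen,13.95,5.0,2.4,0.3,2.4,0.3,2.8,0.3,2.8,0.5
mm-dc-03,mme_killer_whale,dentine_collagen,12.51,5.0,2.2,0.2,2.4,0.3,2.6,0.2,2.4,0.5
mm-dc-04,mme_killer_whale,dentine_collagen,14.03,5.0,2.4,0.3,2.3,0.3,2.8,0.3,2.9,0.5
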