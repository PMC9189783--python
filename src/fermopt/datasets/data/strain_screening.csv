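code,zone_cm,zone_sd,protein_mg,protein_sd,activity_u,activity_sd,improvement_pct
parent,3.0,0.36,123.73,10.65,36209.54,439.24,
UV-15,3.1,0.18,132.11,9.58,41893.09,443.19,15.7
UV-25,3.2,0.11,139.27,12.11,45904.73,463.28,26.78
UV-35,3.6,0.15,179.38,15.37,50784.87,518.37,40.25
kGy-02,3.7,0.26,198.36,16.42,54086.17,419.47,49.37
kGy-04,3.4,0.33,159.64,16.35,54396.62,362.46,50.23
kGy-08,3.3,0.21,148.22,12.36,49889.05,528.47,37.78
UV-15-kGy-04,3.3,0.52,142.67,11.89,49829.29,392.83,37.61
UV-25-kGy-04,3.7,0.47,194.36,17.62,58824.17,653.22,62.46
UV-25-kGy-08,3.7,0.14,201.36,19.17,62291.72,572.81,72.03
kGy-04-UV-25,4.2,0.32,284.93,21.89,85873.38,783.84,137.16
kGy-06-UV-25,3.8,0.38,218.84,16.28,66039.55,689.83,82.38
kGy-08-UV-25,3.9,0.63,223.14,15.15,69825.59,701.26,92.84
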