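{
 "mutant": {
  "biomass": {
   "model": "logistic",
   "X0": 3.29,
   "Xmax": 482.46,
   "mu_max": 0.578,
   "adj_r2": 0.9909,
   "rmse": 17.0,
   "mae": 13.9
  },
  "total_protein": {
   "model": "gompertz",
   "Pmax": 7644.62,
   "r_max": 315.46,
   "t_lag": 5.07,
   "adj_r2": 0.9989,
   "rmse": 81.04,
   "mae": 56.89
  },
  "activity": {
   "model": "gompertz",
   "Pmax": 820953.05,
   "r_max": 44529.23,
   "t_lag": 5.41,
   "adj_r2": 0.9996,
   "rmse": 24.9,
   "mae": 242.49
  },
  "substrate": {
   "model": "gompertz",
   "Pmax": 7250.25,
   "r_max": 397.64,
   "t_lag": 3.38,
   "adj_r2": 0.9997,
   "rmse": 43.17,
   "mae": 34.16
  },
  "yields": {
   "Yp_s": 1.054,
   "Yx_s": 0.067,
   "Yp_x": 0.016,
   "q_p": 0.511,
   "q_s": 0.461
  }
 },
 "wild_type": {
  "biomass": {
   "model": "logistic",
   "X0": 0.61,
   "Xmax": 228.65,
   "mu_max": 0.362,
   "adj_r2": 0.9867,
   "rmse": 10.66,
   "mae": 7.79
  },
  "total_protein": {
   "model": "gompertz",
   "Pmax": 132.05,
   "r_max": 27.55,
   "t_lag": 7.15,
   "adj_r2": 0.9703,
   "rmse": 8.84,
   "mae": 7.11
  },
  "activity": {
   "model": "gompertz",
   "Pmax": 76.73,
   "r_max": 28.16,
   "t_lag": 7.36,
   "adj_r2": 0.984,
   "rmse": 7.25,
   "mae": 6.78
  },
  "substrate": {
   "model": "gompertz",
   "Pmax": 2919.22,
   "r_max": 202.2,
   "t_lag": 2.51,
   "adj_r2": 0.977,
   "rmse": 150.45,
   "mae": 109.31
  },
  "yields": {
   "Yp_s": 0.045,
   "Yx_s": 0.078,
   "Yp_x": 0.00058,
   "q_p": 0.02,
   "q_s": 0.381
  }
 }
}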