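{
 "factors": [
  {
   "name": "cpe",
   "label": "cassava processing effluent",
   "units": "%",
   "low": 45.7,
   "high": 48.1
  },
  {
   "name": "csl",
   "label": "corn steep liquor",
   "units": "%",
   "low": 23.2,
   "high": 24.6
  },
  {
   "name": "casein",
   "label": "casein",
   "units": "%",
   "low": 5.33,
   "high": 6.93
  },
  {
   "name": "mg",
   "label": "Mg2+",
   "units": "g/L",
   "low": 0.16,
   "high": 0.38
  },
  {
   "name": "mn",
   "label": "Mn2+",
   "units": "g/L",
   "low": 0.023,
   "high": 0.039
  }
 ],
 "response": "activity",
 "units": "U",
 "basis": "coded",
 "intercept": 312416,
 "linear": [
  34139.02,
  8494.02,
  3617.09,
  6827.96,
  3105.64
 ],
 "interaction": [
  -4928.91,
  -1433.03,
  12458.59,
  6173.47,
  437.72,
  4314.59,
  6393.34,
  -2139.91,
  1581.59,
  442.72
 ],
 "quadratic": [
  10786.68,
  1898.43,
  178.84,
  6132.32,
  817.53
 ]
}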