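# Default synthetic-cohort parameters: the published per-trait summary statistics
# of the 151-tree Calamansi survey. Quantitative traits are emulated as (correlated)
# normals with these means/SDs; qualitative traits as categoricals with these class
# frequencies (percent; normalized to probabilities on load).
n_individuals: 151
quantitative:
  TH:     {mean: 205.41, sd: 35.24,  minimum: 122.00, maximum: 332.50}
  CB:     {mean: 247.85, sd: 40.82,  minimum: 165.73, maximum: 361.78}
  TH/CB:  {mean: 1.22,   sd: 0.16,   minimum: 0.90,   maximum: 1.69}
  TFD:    {mean: 73.28,  sd: 17.81,  minimum: 14.61,  maximum: 119.06}
  BW:     {mean: 2.59,   sd: 0.17,   minimum: 2.21,   maximum: 3.05}
  BNL:    {mean: 11.16,  sd: 0.92,   minimum: 8.10,   maximum: 13.53}
  YPT:    {mean: 234.52, sd: 103.19, minimum: 25.00,  maximum: 690.00}
  PEL:    {mean: 9.49,   sd: 1.60,   minimum: 6.47,   maximum: 23.83}
  LLL:    {mean: 57.37,  sd: 3.88,   minimum: 47.35,  maximum: 66.25}
  LLW:    {mean: 27.95,  sd: 2.10,   minimum: 22.71,  maximum: 36.90}
  LSI:    {mean: 2.06,   sd: 0.09,   minimum: 1.53,   maximum: 2.33}
  FW:     {mean: 12.54,  sd: 1.57,   minimum: 6.15,   maximum: 17.02}
  FD:     {mean: 28.26,  sd: 1.09,   minimum: 23.97,  maximum: 30.57}
  FL:     {mean: 28.88,  sd: 1.62,   minimum: 23.47,  maximum: 32.00}
  FSI:    {mean: 1.02,   sd: 0.04,   minimum: 0.91,   maximum: 1.16}
  AA:     {mean: 32.29,  sd: 3.62,   minimum: 19.84,  maximum: 44.39}
  TSS:    {mean: 7.56,   sd: 0.39,   minimum: 6.69,   maximum: 8.94}
  TA:     {mean: 8.10,   sd: 0.70,   minimum: 6.04,   maximum: 10.44}
  TSS/TA: {mean: 0.94,   sd: 0.08,   minimum: 0.75,   maximum: 1.17}
  SNF:    {mean: 6.42,   sd: 0.43,   minimum: 5.25,   maximum: 7.50}
  SNPF:   {mean: 7.17,   sd: 1.14,   minimum: 3.92,   maximum: 10.50}
  JR:     {mean: 0.45,   sd: 0.08,   minimum: 0.21,   maximum: 0.55}
  PT:     {mean: 1.22,   sd: 0.12,   minimum: 0.66,   maximum: 1.52}
  OCN:    {mean: 21.10,  sd: 2.97,   minimum: 15.72,  maximum: 30.56}
  PN:     {mean: 4.99,   sd: 0.15,   minimum: 3.67,   maximum: 5.50}
  PL:     {mean: 11.07,  sd: 1.64,   minimum: 7.04,   maximum: 16.87}
  PW:     {mean: 3.72,   sd: 0.51,   minimum: 2.35,   maximum: 4.81}
  SN:     {mean: 21.85,  sd: 2.19,   minimum: 0.00,   maximum: 28.00}
  PIL:    {mean: 6.39,   sd: 1.26,   minimum: 3.12,   maximum: 8.92}
qualitative:
  TS:  {"1": 9.27, "2": 84.11, "3": 6.62}
  TP:  {"1": 23.00, "2": 68.33, "3": 8.67}
  TGV: {"1": 0.00, "2": 23.33, "3": 76.67}
  LB:  {"1": 69.54, "2": 29.80, "3": 0.66}
  FS:  {"1": 0.66, "2": 12.58, "3": 28.48, "4": 0.00, "5": 0.66, "6": 14.57, "7": 3.31, "8": 39.74}
  FBS: {"1": 0.66, "2": 80.79, "3": 14.57, "4": 1.32, "5": 1.99, "6": 0.00, "7": 0.66}
  FTS: {"1": 0.00, "2": 59.60, "3": 32.45, "4": 1.32, "5": 0.00, "6": 6.62}
  PC:  {"1": 5.30, "2": 17.51, "3": 33.63, "4": 37.23, "5": 6.33}
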