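{
 "version": "cn-mw-correlation-v1",
 "source": "Empirical correlation CN_i = -7.8 + 0.302*M_i - 20*N_db (Ramirez-Verduzco et al. 2012, Fuel 91:102-111), with M_i the FAME molecular weight and N_db the number of double bonds.",
 "units": "dimensionless",
 "cetane_numbers": {
  "C12:0": 56.9,
  "C14:0": 65.4,
  "C16:0": 73.9,
  "C16:1": 53.3,
  "C17:1": 57.5,
  "C18:0": 82.4,
  "C18:1": 61.7,
  "C18:2": 41.1,
  "C18:3 n-3": 20.5,
  "C20:0": 90.8,
  "C20:1 n-9": 70.2,
  "C20:3 n-6": 29.0,
  "C20:4 n-6": 8.4,
  "C22:0": 99.3,
  "C22:2": 58.1,
  "C22:4": 16.9,
  "C24:0": 107.8
 }
}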