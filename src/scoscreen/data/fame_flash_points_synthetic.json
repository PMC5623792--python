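{
 "version": "fp-synthetic-linear-v1",
 "synthetic": true,
 "source": "SYNTHETIC estimates: linear homologous-series trend FP_i = 10.5*n_c - 14 degC, anchored near the measured flash point of methyl laurate (~112 degC); double bonds ignored. For demonstration of the per-ester mixture model only; replace with measured values for real work.",
 "units": "degC",
 "flash_points": {
  "C12:0": 112.0,
  "C14:0": 133.0,
  "C16:0": 154.0,
  "C16:1": 154.0,
  "C17:1": 164.5,
  "C18:0": 175.0,
  "C18:1": 175.0,
  "C18:2": 175.0,
  "C18:3 n-3": 175.0,
  "C20:0": 196.0,
  "C20:1 n-9": 196.0,
  "C20:3 n-6": 196.0,
  "C20:4 n-6": 196.0,
  "C22:0": 217.0,
  "C22:2": 217.0,
  "C22:4": 217.0,
  "C24:0": 238.0
 }
}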