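{
 "space": {
  "n_states": 2,
  "n_symbols": 2,
  "dimension": 1,
  "step_cap": 6,
  "mode": "exhaustive",
  "sample_size": null,
  "seed": null
 },
 "total_halting": 3044,
 "fallback_margin": 1.0,
 "fallback_value": 11.571752643503546,
 "fallback_rule": "max covered K + 1.0 bits = 11.571753",
 "moments_cache": {}
}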