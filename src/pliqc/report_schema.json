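{
  "schema_version": 1,
  "required": {
    "id": "str",
    "section": "str",
    "mode": "str",
    "version": "str",
    "timestamp": "str",
    "parameters": "dict",
    "results": "dict",
    "metrics": "dict"
  },
  "fraction_suffixes": [
    "_frac",
    "rho_obs.point", "rho_obs.ci_low", "rho_obs.ci_high",
    "rho_lib.point", "rho_lib.ci_low", "rho_lib.ci_high",
    "alpha_lib.point", "alpha_lib.ci_low", "alpha_lib.ci_high"
  ]
}
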