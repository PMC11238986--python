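{
  "t002": {"concentration": "ng/mL"},
  "t003": {"e_raw": "ng/mL", "e_std": "% of 0-100 scale", "threshold": "ng/mL", "h": "dimensionless"},
  "t004": {"e": "ng/mL", "a_f": "dimensionless", "h": "dimensionless"},
  "t005": {"e": "activity units (0-100 scale)", "h": "dimensionless"},
  "t006": {"e_x": "activity units (0-100 scale)", "h_x": "dimensionless", "e_k": "activity units (0-100 scale)", "h_k": "dimensionless", "alpha": "dimensionless"}
}
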