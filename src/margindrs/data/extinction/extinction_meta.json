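{
 "units": "cm^-1 uM^-1",
 "log_base": "natural",
 "grid_nm": [
  450.0,
  600.0,
  1.0
 ],
 "note": "Synthetic band-model extinction curves (Gaussian bands) standing in for laboratory compilations; constructed for forward/inverse self-consistent simulation, not for absolute quantitation.",
 "files": {
  "hbo2": "synthetic_hbo2.tsv",
  "hbh": "synthetic_hbh.tsv",
  "beta_carotene": "synthetic_beta_carotene.tsv",
  "patent_blue_dye": "synthetic_patent_blue_dye.tsv"
 }
}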