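{
 "intercept": 35.7,
 "entries": [
  {"snp_id": "rs709158", "gene": "PPARG", "coding": "additive", "coefficient": 16.8, "vip": 1.35},
  {"snp_id": "rs1561166", "gene": "ABCA1", "coding": "dominant", "coefficient": 36.4, "vip": 1.34},
  {"snp_id": "rs1783225", "gene": "BUD13", "coding": "dominant", "coefficient": 25.0, "vip": 1.29},
  {"snp_id": "rs12686004", "gene": "ABCA1", "coding": "dominant", "coefficient": 27.3, "vip": 1.28},
  {"snp_id": "rs1648364", "gene": "BUD13", "coding": "dominant", "coefficient": 27.2, "vip": 1.27},
  {"snp_id": "rs2275542", "gene": "ABCA1", "coding": "dominant", "coefficient": 21.9, "vip": 1.24},
  {"snp_id": "rs4743764", "gene": "ABCA1", "coding": "dominant", "coefficient": 22.3, "vip": 1.20},
  {"snp_id": "rs13076933", "gene": "PPARG", "coding": "dominant", "coefficient": 21.0, "vip": 1.20},
  {"snp_id": "rs3211958", "gene": "CD36", "coding": "additive", "coefficient": 15.9, "vip": 1.19},
  {"snp_id": "rs3773161", "gene": "MGLL", "coding": "dominant", "coefficient": 31.7, "vip": 1.17}
 ]
}
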