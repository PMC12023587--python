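{
  "mTOR_pathway": ["PTEN", "PIK3CA", "PIK3R1", "AKT1", "MTOR", "TSC1", "TSC2"],
  "SWI_SNF_complex": ["ARID1A", "ARID1B", "ARID2", "SMARCA4", "SMARCB1", "PBRM1"],
  "H3K4_methyltransferase": ["KMT2A", "KMT2B", "KMT2C", "KMT2D", "SETD1A", "SETD1B"]
}
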