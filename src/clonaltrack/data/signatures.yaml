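# T-cell functional gene signatures used for cluster scoring and phenotype
# annotation.  Marker sets follow the standard human nomenclature for
# effector, interferon-responsive, exhausted, precursor-exhausted (GZMK-high),
# tissue-resident memory (positive and recirculation/negative markers),
# regulatory, naive, and follicular-helper T-cell programs.  CD39 is ENTPD1.
cytotoxic: [CX3CR1, PRF1, GNLY, NKG7, GZMB, KLRD1, FGFBP2]
IFN_response: [IFIT2, IFIT3, OASL, ISG15]
proliferation: [MKI67, TOP2A, STMN1, TYMS]
exhaustion: [PDCD1, HAVCR2, LAYN, TIGIT, LAG3, ENTPD1]
TPEX: [GZMK]
TRM_pos: [CRTAM, RGS1, DUSP6, CD69, CXCR6, TNFRSF9]
TRM_neg: [STK38, KLF2, RIPOR2]
Treg: [IL2RA, FOXP3]
TN: [CCR7, SELL, LEF1, TCF7]
TFH: [BCL6, CXCL13]
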