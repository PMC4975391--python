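{
 "table1_tsc_variants.tsv": "a8983e0c868dd769d6e43bbaa83e29ae186fa3f2262b14dc237cdff4b399cb66",
 "table2_other_somatic.tsv": "191686b5601f1584cf73c726d1e3575cab25c474f7909989d10afdb76d4f5a2c",
 "synthetic_p13_loh_regions.tsv": "819cd3fadd187e94acc96de64f3105c66d11dfd4cdbacbc0dead545d00490a89"
}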