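gda/summary?gene_ncbi_id=1001,1002,1003&format=json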