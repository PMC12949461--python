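projects/synthetic/models:search?symbols=GS1,GS2,GS3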