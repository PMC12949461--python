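network?identifiers=9606.ENSP00001000001%0d9606.ENSP00001000002%0d9606.ENSP00001000003&species=9606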