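[{"preferredName_A": "ENSP00001000001", "preferredName_B": "ENSP00001000002", "score": 0.835, "stringId_A": "9606.ENSP00001000001", "stringId_B": "9606.ENSP00001000002"}, {"preferredName_A": "ENSP00001000002", "preferredName_B": "ENSP00001000003", "score": 0.776, "stringId_A": "9606.ENSP00001000002", "stringId_B": "9606.ENSP00001000003"}]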