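{"models": [{"elements": ["GS1", "GS2", "GS3"], "idObject": 101, "name": "synthetic interferon signalling map"}, {"elements": ["GS2"], "idObject": 102, "name": "synthetic cytokine storm map"}, {"elements": ["GS1", "GS2"], "idObject": 103, "name": "synthetic mitochondrial dysfunction map"}]}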