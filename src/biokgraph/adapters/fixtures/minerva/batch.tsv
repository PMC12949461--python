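ENTREZ:1001	GS1
ENTREZ:1002	GS2
ENTREZ:1003	GS3
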