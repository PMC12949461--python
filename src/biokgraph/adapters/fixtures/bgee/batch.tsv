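ENTREZ:1001	ENSG00001000001
ENTREZ:1002	ENSG00001000002
ENTREZ:1003	ENSG00001000003
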