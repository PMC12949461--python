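ENTREZ:1001	1001
ENTREZ:1002	1002
ENTREZ:1003	1003
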