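anchor_key	subject_key	subject_type	relation	object_key	object_type	subject_attributes	object_attributes	edge_attributes	source_field_map
ENTREZ:1001	ENTREZ:1001	gene	part_of	MINERVA:101	pathway	{}	"{""name"": ""synthetic interferon signalling map""}"	{}	"{""name"": ""name""}"
ENTREZ:1001	ENTREZ:1001	gene	part_of	MINERVA:103	pathway	{}	"{""name"": ""synthetic mitochondrial dysfunction map""}"	{}	"{""name"": ""name""}"
ENTREZ:1002	ENTREZ:1002	gene	part_of	MINERVA:101	pathway	{}	"{""name"": ""synthetic interferon signalling map""}"	{}	"{""name"": ""name""}"
ENTREZ:1002	ENTREZ:1002	gene	part_of	MINERVA:102	pathway	{}	"{""name"": ""synthetic cytokine storm map""}"	{}	"{""name"": ""name""}"
ENTREZ:1002	ENTREZ:1002	gene	part_of	MINERVA:103	pathway	{}	"{""name"": ""synthetic mitochondrial dysfunction map""}"	{}	"{""name"": ""name""}"
ENTREZ:1003	ENTREZ:1003	gene	part_of	MINERVA:101	pathway	{}	"{""name"": ""synthetic interferon signalling map""}"	{}	"{""name"": ""name""}"
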