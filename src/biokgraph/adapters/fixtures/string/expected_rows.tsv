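anchor_key	subject_key	subject_type	relation	object_key	object_type	subject_attributes	object_attributes	edge_attributes	source_field_map
ENTREZ:1001	ENTREZ:1001	gene	interacts_with	ENTREZ:1002	gene	{}	{}	"{""score"": 0.835}"	"{""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	interacts_with	ENTREZ:1003	gene	{}	{}	"{""score"": 0.776}"	"{""score"": ""score""}"
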