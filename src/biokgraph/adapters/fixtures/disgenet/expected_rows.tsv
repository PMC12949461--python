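anchor_key	subject_key	subject_type	relation	object_key	object_type	subject_attributes	object_attributes	edge_attributes	source_field_map
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000001	disease	{}	"{""name"": ""synthetic post-viral fatigue syndrome""}"	"{""score"": 0.878}"	"{""name"": ""disease_name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000002	disease	{}	"{""name"": ""synthetic chronic dyspnea disorder""}"	"{""score"": 0.378}"	"{""name"": ""disease_name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000002	disease	{}	"{""name"": ""synthetic chronic dyspnea disorder""}"	"{""score"": 0.657}"	"{""name"": ""disease_name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000003	disease	{}	"{""name"": ""synthetic myalgia condition""}"	"{""score"": 0.615}"	"{""name"": ""disease_name"", ""score"": ""score""}"
ENTREZ:1003	ENTREZ:1003	gene	associated_with	UMLS:C5000003	disease	{}	"{""name"": ""synthetic myalgia condition""}"	"{""score"": 0.166}"	"{""name"": ""disease_name"", ""score"": ""score""}"
ENTREZ:1003	ENTREZ:1003	gene	associated_with	UMLS:C5000005	disease	{}	"{""name"": ""synthetic systemic inflammation syndrome""}"	"{""score"": 0.107}"	"{""name"": ""disease_name"", ""score"": ""score""}"
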