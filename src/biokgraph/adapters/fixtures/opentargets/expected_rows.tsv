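anchor_key	subject_key	subject_type	relation	object_key	object_type	subject_attributes	object_attributes	edge_attributes	source_field_map
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000001	disease	{}	"{""name"": ""synthetic post-viral fatigue syndrome""}"	"{""score"": 0.259}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000002	disease	{}	"{""name"": ""synthetic chronic dyspnea disorder""}"	"{""score"": 0.946}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000003	disease	{}	"{""name"": ""synthetic myalgia condition""}"	"{""score"": 0.949}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000004	disease	{}	"{""name"": ""synthetic cognitive dysfunction""}"	"{""score"": 0.794}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	associated_with	UMLS:C5000005	disease	{}	"{""name"": ""synthetic systemic inflammation syndrome""}"	"{""score"": 0.152}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1001	ENTREZ:1001	gene	part_of	REACTOME:R-HSA-9000001	pathway	{}	"{""name"": ""synthetic interferon signalling""}"	{}	"{""name"": ""name""}"
ENTREZ:1001	ENTREZ:1001	gene	part_of	REACTOME:R-HSA-9000002	pathway	{}	"{""name"": ""synthetic cytokine cascade""}"	{}	"{""name"": ""name""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000001	disease	{}	"{""name"": ""synthetic post-viral fatigue syndrome""}"	"{""score"": 0.528}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000002	disease	{}	"{""name"": ""synthetic chronic dyspnea disorder""}"	"{""score"": 0.903}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000003	disease	{}	"{""name"": ""synthetic myalgia condition""}"	"{""score"": 0.411}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000004	disease	{}	"{""name"": ""synthetic cognitive dysfunction""}"	"{""score"": 0.225}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	associated_with	UMLS:C5000005	disease	{}	"{""name"": ""synthetic systemic inflammation syndrome""}"	"{""score"": 0.955}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1002	ENTREZ:1002	gene	part_of	REACTOME:R-HSA-9000001	pathway	{}	"{""name"": ""synthetic interferon signalling""}"	{}	"{""name"": ""name""}"
ENTREZ:1002	ENTREZ:1002	gene	part_of	REACTOME:R-HSA-9000002	pathway	{}	"{""name"": ""synthetic cytokine cascade""}"	{}	"{""name"": ""name""}"
ENTREZ:1003	ENTREZ:1003	gene	associated_with	UMLS:C5000004	disease	{}	"{""name"": ""synthetic cognitive dysfunction""}"	"{""score"": 0.661}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1003	ENTREZ:1003	gene	associated_with	UMLS:C5000005	disease	{}	"{""name"": ""synthetic systemic inflammation syndrome""}"	"{""score"": 0.119}"	"{""name"": ""disease.name"", ""score"": ""score""}"
ENTREZ:1003	ENTREZ:1003	gene	part_of	REACTOME:R-HSA-9000002	pathway	{}	"{""name"": ""synthetic cytokine cascade""}"	{}	"{""name"": ""name""}"
ENTREZ:1001	PUBCHEM:90000001	compound	inhibits	ENTREZ:1001	gene	"{""name"": ""synthetin"", ""raw_mechanism_of_action"": ""inhibitor""}"	{}	{}	"{""name"": ""drug.name""}"
ENTREZ:1001	PUBCHEM:90000001	compound	treats	UMLS:C5000004	disease	"{""name"": ""synthetin""}"	{}	{}	{}
ENTREZ:1001	PUBCHEM:90000002	compound	activates	ENTREZ:1001	gene	"{""name"": ""fabricol"", ""raw_mechanism_of_action"": ""agonist""}"	{}	{}	"{""name"": ""drug.name""}"
ENTREZ:1002	PUBCHEM:90000002	compound	activates	ENTREZ:1002	gene	"{""name"": ""fabricol"", ""raw_mechanism_of_action"": ""agonist""}"	{}	{}	"{""name"": ""drug.name""}"
ENTREZ:1001	PUBCHEM:90000002	compound	treats	UMLS:C5000001	disease	"{""name"": ""fabricol""}"	{}	{}	{}
ENTREZ:1002	PUBCHEM:90000002	compound	treats	UMLS:C5000004	disease	"{""name"": ""fabricol""}"	{}	{}	{}
ENTREZ:1001	PUBCHEM:90000003	compound	inhibits	ENTREZ:1001	gene	"{""name"": ""mockamide"", ""raw_mechanism_of_action"": ""inhibitor""}"	{}	{}	"{""name"": ""drug.name""}"
ENTREZ:1001	PUBCHEM:90000003	compound	treats	UMLS:C5000005	disease	"{""name"": ""mockamide""}"	{}	{}	{}
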