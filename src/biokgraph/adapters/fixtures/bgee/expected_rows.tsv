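anchor_key	subject_key	subject_type	relation	object_key	object_type	subject_attributes	object_attributes	edge_attributes	source_field_map
ENTREZ:1001	ENTREZ:1001	gene	expressed_by	UBERON:0000948	anatomical_entity	{}	"{""name"": ""heart""}"	"{""developmental_stage"": ""embryonic"", ""expression_level"": 48.06, ""over_expressed"": true}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
ENTREZ:1001	ENTREZ:1001	gene	expressed_by	UBERON:0002048	anatomical_entity	{}	"{""name"": ""lung""}"	"{""developmental_stage"": ""embryonic"", ""expression_level"": 47.42, ""over_expressed"": false}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
ENTREZ:1001	ENTREZ:1001	gene	expressed_by	UBERON:0002106	anatomical_entity	{}	"{""name"": ""spleen""}"	"{""developmental_stage"": ""juvenile"", ""expression_level"": 1.93, ""over_expressed"": false}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
ENTREZ:1002	ENTREZ:1002	gene	expressed_by	UBERON:0000948	anatomical_entity	{}	"{""name"": ""heart""}"	"{""developmental_stage"": ""juvenile"", ""expression_level"": 50.99, ""over_expressed"": false}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
ENTREZ:1003	ENTREZ:1003	gene	expressed_by	UBERON:0000948	anatomical_entity	{}	"{""name"": ""heart""}"	"{""developmental_stage"": ""juvenile"", ""expression_level"": 40.86, ""over_expressed"": true}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
ENTREZ:1003	ENTREZ:1003	gene	expressed_by	UBERON:0000955	anatomical_entity	{}	"{""name"": ""brain""}"	"{""developmental_stage"": ""juvenile"", ""expression_level"": 62.51, ""over_expressed"": false}"	"{""developmental_stage"": ""stage"", ""expression_level"": ""expressionLevel"", ""over_expressed"": ""direction""}"
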