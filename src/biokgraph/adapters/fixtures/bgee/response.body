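{"head": {"vars": ["gene", "anat", "anatName", "expressionLevel", "stage", "direction"]}, "results": {"bindings": [{"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0000948"}, "anatName": {"type": "literal", "value": "heart"}, "direction": {"type": "literal", "value": "over"}, "expressionLevel": {"type": "literal", "value": "48.06"}, "gene": {"type": "literal", "value": "ENSG00001000001"}, "stage": {"type": "literal", "value": "embryonic"}}, {"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0002048"}, "anatName": {"type": "literal", "value": "lung"}, "direction": {"type": "literal", "value": "under"}, "expressionLevel": {"type": "literal", "value": "47.42"}, "gene": {"type": "literal", "value": "ENSG00001000001"}, "stage": {"type": "literal", "value": "embryonic"}}, {"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0002106"}, "anatName": {"type": "literal", "value": "spleen"}, "direction": {"type": "literal", "value": "under"}, "expressionLevel": {"type": "literal", "value": "1.93"}, "gene": {"type": "literal", "value": "ENSG00001000001"}, "stage": {"type": "literal", "value": "juvenile"}}, {"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0000948"}, "anatName": {"type": "literal", "value": "heart"}, "direction": {"type": "literal", "value": "under"}, "expressionLevel": {"type": "literal", "value": "50.99"}, "gene": {"type": "literal", "value": "ENSG00001000002"}, "stage": {"type": "literal", "value": "juvenile"}}, {"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0000948"}, "anatName": {"type": "literal", "value": "heart"}, "direction": {"type": "literal", "value": "over"}, "expressionLevel": {"type": "literal", "value": "40.86"}, "gene": {"type": "literal", "value": "ENSG00001000003"}, "stage": {"type": "literal", "value": "juvenile"}}, {"anat": {"type": "uri", "value": "http://purl.obolibrary.org/obo/UBERON_0000955"}, "anatName": {"type": "literal", "value": "brain"}, "direction": {"type": "literal", "value": "under"}, "expressionLevel": {"type": "literal", "value": "62.51"}, "gene": {"type": "literal", "value": "ENSG00001000003"}, "stage": {"type": "literal", "value": "juvenile"}}]}}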