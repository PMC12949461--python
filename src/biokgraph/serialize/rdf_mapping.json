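{
  "version": "1",
  "node_classes": {
    "gene": "http://purl.obolibrary.org/obo/SO_0000704",
    "disease": "http://purl.obolibrary.org/obo/DOID_4",
    "compound": "http://purl.obolibrary.org/obo/CHEBI_23367",
    "anatomical_entity": "http://purl.obolibrary.org/obo/UBERON_0001062",
    "pathway": "http://purl.obolibrary.org/obo/PW_0000001",
    "molecular_function": "http://purl.obolibrary.org/obo/GO_0003674",
    "biological_process": "http://purl.obolibrary.org/obo/GO_0008150",
    "cellular_component": "http://purl.obolibrary.org/obo/GO_0005575",
    "side_effect": "http://purl.obolibrary.org/obo/OAE_0000001",
    "homolog": "http://semanticscience.org/resource/SIO_010077",
    "phenotype": "http://purl.obolibrary.org/obo/UPHENO_0001001",
    "mirna": "http://purl.obolibrary.org/obo/SO_0000276",
    "transcription_factor": "http://purl.obolibrary.org/obo/NCIT_C17207",
    "mitochondrial_pathway": "http://purl.obolibrary.org/obo/PW_0000002",
    "key_event": "http://aopkb.org/aop_ontology#KeyEvent",
    "molecular_initiating_event": "http://aopkb.org/aop_ontology#MolecularInitiatingEvent",
    "adverse_outcome_pathway": "http://aopkb.org/aop_ontology#AdverseOutcomePathway",
    "adverse_outcome": "http://aopkb.org/aop_ontology#AdverseOutcome"
  },
  "relation_predicates": {
    "interacts_with": "http://purl.obolibrary.org/obo/RO_0002434",
    "part_of": "http://purl.obolibrary.org/obo/BFO_0000050",
    "associated_with": "http://semanticscience.org/resource/SIO_000001",
    "expressed_by": "http://purl.obolibrary.org/obo/RO_0002206",
    "activates": "http://purl.obolibrary.org/obo/RO_0018027",
    "inhibits": "http://purl.obolibrary.org/obo/RO_0018029",
    "treats": "http://purl.obolibrary.org/obo/RO_0002606",
    "has_side_effect": "http://semanticscience.org/resource/SIO_001123",
    "upstream_of": "http://purl.obolibrary.org/obo/RO_0002411",
    "downstream_of": "http://purl.obolibrary.org/obo/RO_0002427"
  },
  "measurement": {
    "has_measurement_value": "http://semanticscience.org/resource/SIO_000216",
    "measurement_value_class": "http://semanticscience.org/resource/SIO_000070",
    "has_value": "http://semanticscience.org/resource/SIO_000300"
  },
  "association": {
    "association_class": "http://semanticscience.org/resource/SIO_000897",
    "has_part": "http://semanticscience.org/resource/SIO_000028"
  }
}
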