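PREFIX genex: <http://purl.org/genex#>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?gene ?anat ?anatName ?expressionLevel ?stage ?direction
WHERE {
  VALUES ?gene { "ENSG00001000001" "ENSG00001000002" "ENSG00001000003" }
  ?expression genex:hasSequenceUnit ?gene .
  ?expression genex:hasAnatomicalEntity ?anat .
  ?anat rdfs:label ?anatName .
  ?expression genex:hasExpressionLevel ?expressionLevel .
  ?expression genex:hasDevelopmentalStage ?stage .
  ?expression genex:hasDirection ?direction .
}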