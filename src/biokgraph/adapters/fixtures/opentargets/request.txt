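query annotateTargets { t0: target(ensemblId: "ENSG00001000001") { id approvedSymbol associatedDiseases { rows { disease { id name dbXRefs } score } } knownDrugs { rows { drug { id name pubchemCid } mechanismOfAction disease { id dbXRefs } } } pathways { id name } } t1: target(ensemblId: "ENSG00001000002") { id approvedSymbol associatedDiseases { rows { disease { id name dbXRefs } score } } knownDrugs { rows { drug { id name pubchemCid } mechanismOfAction disease { id dbXRefs } } } pathways { id name } } t2: target(ensemblId: "ENSG00001000003") { id approvedSymbol associatedDiseases { rows { disease { id name dbXRefs } score } } knownDrugs { rows { drug { id name pubchemCid } mechanismOfAction disease { id dbXRefs } } } pathways { id name } } }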