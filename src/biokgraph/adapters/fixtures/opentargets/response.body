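{"data": {"t0": {"approvedSymbol": "SYM0", "associatedDiseases": {"rows": [{"disease": {"dbXRefs": ["UMLS:C5000001"], "id": "EFO_900001", "name": "synthetic post-viral fatigue syndrome"}, "score": 0.259}, {"disease": {"dbXRefs": ["UMLS:C5000002"], "id": "EFO_900002", "name": "synthetic chronic dyspnea disorder"}, "score": 0.946}, {"disease": {"dbXRefs": ["UMLS:C5000003"], "id": "EFO_900003", "name": "synthetic myalgia condition"}, "score": 0.949}, {"disease": {"dbXRefs": ["UMLS:C5000004"], "id": "EFO_900004", "name": "synthetic cognitive dysfunction"}, "score": 0.794}, {"disease": {"dbXRefs": ["UMLS:C5000005"], "id": "EFO_900005", "name": "synthetic systemic inflammation syndrome"}, "score": 0.152}]}, "id": "ENSG00001000001", "knownDrugs": {"rows": [{"disease": {"dbXRefs": ["UMLS:C5000004"], "id": "EFO_900004"}, "drug": {"id": "CHEMBL900001", "name": "synthetin", "pubchemCid": "90000001"}, "mechanismOfAction": "inhibitor"}, {"disease": {"dbXRefs": ["UMLS:C5000001"], "id": "EFO_900001"}, "drug": {"id": "CHEMBL900002", "name": "fabricol", "pubchemCid": "90000002"}, "mechanismOfAction": "agonist"}, {"disease": {"dbXRefs": ["UMLS:C5000005"], "id": "EFO_900005"}, "drug": {"id": "CHEMBL900003", "name": "mockamide", "pubchemCid": "90000003"}, "mechanismOfAction": "inhibitor"}]}, "pathways": [{"id": "R-HSA-9000001", "name": "synthetic interferon signalling"}, {"id": "R-HSA-9000002", "name": "synthetic cytokine cascade"}]}, "t1": {"approvedSymbol": "SYM1", "associatedDiseases": {"rows": [{"disease": {"dbXRefs": ["UMLS:C5000001"], "id": "EFO_900001", "name": "synthetic post-viral fatigue syndrome"}, "score": 0.528}, {"disease": {"dbXRefs": ["UMLS:C5000002"], "id": "EFO_900002", "name": "synthetic chronic dyspnea disorder"}, "score": 0.903}, {"disease": {"dbXRefs": ["UMLS:C5000003"], "id": "EFO_900003", "name": "synthetic myalgia condition"}, "score": 0.411}, {"disease": {"dbXRefs": ["UMLS:C5000004"], "id": "EFO_900004", "name": "synthetic cognitive dysfunction"}, "score": 0.225}, {"disease": {"dbXRefs": ["UMLS:C5000005"], "id": "EFO_900005", "name": "synthetic systemic inflammation syndrome"}, "score": 0.955}]}, "id": "ENSG00001000002", "knownDrugs": {"rows": [{"disease": {"dbXRefs": ["UMLS:C5000004"], "id": "EFO_900004"}, "drug": {"id": "CHEMBL900002", "name": "fabricol", "pubchemCid": "90000002"}, "mechanismOfAction": "agonist"}]}, "pathways": [{"id": "R-HSA-9000001", "name": "synthetic interferon signalling"}, {"id": "R-HSA-9000002", "name": "synthetic cytokine cascade"}]}, "t2": {"approvedSymbol": "SYM2", "associatedDiseases": {"rows": [{"disease": {"dbXRefs": ["UMLS:C5000004"], "id": "EFO_900004", "name": "synthetic cognitive dysfunction"}, "score": 0.661}, {"disease": {"dbXRefs": ["UMLS:C5000005"], "id": "EFO_900005", "name": "synthetic systemic inflammation syndrome"}, "score": 0.119}]}, "id": "ENSG00001000003", "knownDrugs": {"rows": []}, "pathways": [{"id": "R-HSA-9000002", "name": "synthetic cytokine cascade"}]}}}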