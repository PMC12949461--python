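{"payload": [{"disease_name": "synthetic post-viral fatigue syndrome", "disease_umls": "C5000001", "gene_ncbi_id": 1001, "score": 0.878}, {"disease_name": "synthetic chronic dyspnea disorder", "disease_umls": "C5000002", "gene_ncbi_id": 1001, "score": 0.378}, {"disease_name": "synthetic chronic dyspnea disorder", "disease_umls": "C5000002", "gene_ncbi_id": 1002, "score": 0.657}, {"disease_name": "synthetic myalgia condition", "disease_umls": "C5000003", "gene_ncbi_id": 1002, "score": 0.615}, {"disease_name": "synthetic myalgia condition", "disease_umls": "C5000003", "gene_ncbi_id": 1003, "score": 0.166}, {"disease_name": "synthetic systemic inflammation syndrome", "disease_umls": "C5000005", "gene_ncbi_id": 1003, "score": 0.107}], "status": "OK"}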