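"""Synthetic candidate-object pools used by fixture response synthesis.

These are NOT real database contents: identifiers and names are invented
(clearly marked "synthetic") and exist only so offline fixture responses
have realistic shapes and stable identifiers. Accession patterns follow
each namespace's conventions (UMLS CUIs, EFO/CHEMBL ids, Reactome stable
ids, UBERON ids) so parsers exercise the same code paths as live data.
"""

from __future__ import annotations

#: (UMLS CUI, label) — synthetic disease pool.
DISEASES: tuple[tuple[str, str], ...] = (
    ("C5000001", "synthetic post-viral fatigue syndrome"),
    ("C5000002", "synthetic chronic dyspnea disorder"),
    ("C5000003", "synthetic myalgia condition"),
    ("C5000004", "synthetic cognitive dysfunction"),
    ("C5000005", "synthetic systemic inflammation syndrome"),
)

#: (EFO id, UMLS CUI, label) — the same diseases as OpenTargets-shaped
#: records, carrying their UMLS cross-reference.
EFO_DISEASES: tuple[tuple[str, str, str], ...] = tuple(
    (f"EFO_{900001 + i}", cui, label) for i, (cui, label) in enumerate(DISEASES)
)

#: (ChEMBL id, PubChem CID, label, mechanism) — synthetic drug pool.
DRUGS: tuple[tuple[str, str, str, str], ...] = (
    ("CHEMBL900001", "90000001", "synthetin", "inhibitor"),
    ("CHEMBL900002", "90000002", "fabricol", "agonist"),
    ("CHEMBL900003", "90000003", "mockamide", "inhibitor"),
)

#: (Reactome stable id, label) — synthetic pathway pool (OpenTargets-shaped).
REACTOME_PATHWAYS: tuple[tuple[str, str], ...] = (
    ("R-HSA-9000001", "synthetic interferon signalling"),
    ("R-HSA-9000002", "synthetic cytokine cascade"),
)

#: (MINERVA model id, label) — synthetic disease-map pathway pool.
MINERVA_MODELS: tuple[tuple[int, str], ...] = (
    (101, "synthetic interferon signalling map"),
    (102, "synthetic cytokine storm map"),
    (103, "synthetic mitochondrial dysfunction map"),
)

#: (UBERON accession, label) — anatomical entities (Bgee-shaped).
ANATOMICAL_ENTITIES: tuple[tuple[str, str], ...] = (
    ("0000948", "heart"),
    ("0002048", "lung"),
    ("0000955", "brain"),
    ("0002106", "spleen"),
)

#: Developmental stages cycled through by Bgee-shaped fixtures.
STAGES: tuple[str, ...] = ("embryonic", "juvenile", "adult")
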