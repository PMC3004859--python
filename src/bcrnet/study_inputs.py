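"""Published name sets and parameters of the immature-B-cell (CH1) study.

These are printed inputs of the analysis — gene and TF symbols, the panel
of probed signaling intermediates, ortholog mappings and alias spellings —
collected here so the pipeline stages can be driven end to end.
"""

from __future__ import annotations

#: early genes upregulated >2-fold within 1 h of BCR cross-linking in CH1
#: (immature-type) cells
EARLY_INDUCED_GENES = {
    "ZFP36", "CD69", "DDIT3", "ATF3", "EGR1", "FOSB",
    "RGS1", "AXUD1", "TNF", "CD274", "DUSP2",
}

#: of those, the genes also induced in BCR-stimulated mature (A20) B cells —
#: unlikely to drive the G1-arrest phenotype, hence subtracted out
MATURE_SHARED_GENES = {"EGR1", "FOSB", "CD69", "TNF"}

#: mixed spellings occurring across tables and figures
GENE_ALIASES = {"TNFA": "TNF", "NAFTC2": "NFATC2", "SP1": "SP1"}

#: the sixteen candidate regulators of the eleven early genes
#: (promoter scan + literature curation)
CANDIDATE_TFS = {
    # array-modulated (activated or suppressed by anti-IgM)
    "TBP", "NFKB1", "TRP53", "FOSL1", "MZF1", "SP1", "NFATC2",
    # candidates whose array activity was unaffected
    "CREB1", "MYC", "YY1", "SRF", "ETS1", "STAT3", "ELK1", "E2F1", "GATA1",
}

#: the seven candidates that the TF array showed to be modulated
MODULATED_CANDIDATE_TFS = {"TBP", "NFKB1", "TRP53", "FOSL1", "MZF1", "SP1", "NFATC2"}
ARRAY_ACTIVATED_CANDIDATES = {"TBP", "NFKB1", "TRP53", "FOSL1"}
ARRAY_SUPPRESSED_CANDIDATES = {"MZF1", "SP1", "NFATC2"}

#: western-blot panel: fourteen intermediates showing BCR-dependent
#: phosphorylation, with the eight reaching at least 2-fold over basal
ACTIVATED_INTERMEDIATES = (
    "Raf1", "ERK-1/2", "MEK-1/2", "p38", "JNK", "CAMKII", "Lyn", "Akt",
)
WEAK_INTERMEDIATES = ("Syk", "Bad", "GSK3b", "PLCg", "PKCd", "PKA")

#: mouse intermediate -> human ortholog symbol used by the interactome
ORTHOLOG_MAP = {
    "Raf1": "RAF1",
    "ERK-1/2": "MAPK1",
    "MEK-1/2": "MAP2K1",
    "p38": "MAPK14",
    "JNK": "MAPK8",
    "CAMKII": "CAMK2G",
    "Lyn": "LYN",
    "Akt": "AKT1",
    "Syk": "SYK",
    "Bad": "BAD",
    "GSK3b": "GSK3B",
    "PLCg": "PLCG2",
    "PKCd": "PRKCD",
    "PKA": "PRKACA",
}

#: receptor subunits collapsed into the single BCR complex node
BCR_SUBUNITS = {"CD79A", "CD79B"}
BCR_NODE = "BCR"

#: array geometry
N_ARRAY_TFS = 345
N_ARRAY_ACTIVATED = 36
N_ARRAY_SUPPRESSED = 30
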