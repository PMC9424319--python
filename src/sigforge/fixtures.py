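"""Packaged gene-list fixtures.

ET-9 is the nine-gene epigenetic tumor signature: super-enhancer-associated,
HDAC1/7 co-regulated genes whose alteration status stratifies breast cancer
survival. The list is ordered as published (Entrez id order of the source
table).
"""

from .io import GeneSignature

ET9_GENES = (
    "ADGRG1",
    "FIBCD1",
    "GDPD5",
    "SUSD2",
    "CACNG4",
    "CX3CL1",
    "IGFBP5",
    "MAP6",
    "CCDC69",
)

#: Genes found prognostic as single markers and merged into ET-9 alongside
#: the SGR / k-TSP core.
ET9_SINGLE_MARKERS = ("SUSD2", "ADGRG1")


def et9() -> GeneSignature:
    """The ET-9 prognostic signature as a GeneSignature."""
    return GeneSignature("ET-9", list(ET9_GENES))
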