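"""Published mitochondrial CDS nucleotide lengths for four Calanus species.

These printed gene lengths (base pairs) are shipped as package data so that
the codon-level accounting -- amino-acid chain lengths under the
incomplete-stop rule, per-gene relative standard deviations, and the
incomplete-stop census -- can be reproduced without downloading the deposited
accessions.  Lengths not divisible by three correspond to genes whose stop
codon is completed by transcript polyadenylation.
"""

from __future__ import annotations

#: The 13 protein-coding genes in the conventional reporting order.
CDS_GENES = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nd1", "nd2", "nd3", "nd4", "nd4l", "nd5", "nd6",
)

#: gene -> nucleotide length (bp), per species.
CDS_LENGTHS_BP: dict[str, dict[str, int]] = {
    "C_glacialis": {
        "atp6": 714, "atp8": 162, "cox1": 1557, "cox2": 705, "cox3": 792,
        "cytb": 1133, "nd1": 919, "nd2": 969, "nd3": 354, "nd4": 1302,
        "nd4l": 336, "nd5": 1711, "nd6": 474,
    },
    "C_finmarchicus": {
        "atp6": 712, "atp8": 162, "cox1": 1557, "cox2": 705, "cox3": 792,
        "cytb": 1132, "nd1": 919, "nd2": 969, "nd3": 354, "nd4": 1302,
        "nd4l": 336, "nd5": 1712, "nd6": 483,
    },
    "C_hyperboreus": {
        "atp6": 708, "atp8": 159, "cox1": 1546, "cox2": 704, "cox3": 792,
        "cytb": 1137, "nd1": 915, "nd2": 969, "nd3": 354, "nd4": 1302,
        "nd4l": 336, "nd5": 1710, "nd6": 474,
    },
    "C_sinicus": {
        "atp6": 711, "atp8": 162, "cox1": 1548, "cox2": 705, "cox3": 792,
        "cytb": 1137, "nd1": 917, "nd2": 969, "nd3": 354, "nd4": 1302,
        "nd4l": 336, "nd5": 1723, "nd6": 480,
    },
}

SPECIES = tuple(CDS_LENGTHS_BP)

#: The two newly reported species (the remaining two are the previously
#: published comparators).
NEW_SPECIES = ("C_glacialis", "C_finmarchicus")
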