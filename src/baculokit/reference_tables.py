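"""Editable reference tables for gene-content classification.

These tables encode field-standard gene lists for baculovirus
comparative genomics.  ``CORE_GENES`` is the set of genes found in every
sequenced baculovirus genome and used for concatenated phylogenies.
``GV_SPECIFIC_ORFS`` and ``UNIQUE_ORFS`` list, by ORF serial on the
focal granulovirus genome, the betabaculovirus-exclusive gene set and
the ORFs with no homologue elsewhere in the family.  They ship as data,
not logic, so users can maintain them as annotations evolve.
"""

from __future__ import annotations

# The 31 genes present in all sequenced baculovirus genomes.
CORE_GENES: tuple[str, ...] = (
    # transcription
    "lef-4", "lef-8", "lef-9", "p47", "lef-5", "vlf-1",
    # replication
    "dnapol", "lef-1", "lef-2", "helicase-1",
    # packaging / assembly / structure
    "p6.9", "vp39", "vp1054", "vp91", "gp41", "odv-ec43", "odv-e18",
    "p74", "pif-1", "pif-2", "pif-3", "pif-4", "pif-5", "pif-6",
    "38k", "ac53", "ac78", "ac81", "p33", "desmoplakin",
    # auxiliary
    "alk-exo",
)

# Betabaculovirus-exclusive gene set, by focal-genome ORF serial.
GV_SPECIFIC_ORFS: tuple[int, ...] = (
    7, 8, 17, 21, 22, 25, 37, 40, 43, 44, 62, 70, 73, 94, 95, 110, 111,
    126, 131,
)

# ORFs unique to the focal genome within the family, by serial.
UNIQUE_ORFS: tuple[int, ...] = (
    4, 9, 12, 16, 18, 19, 20, 23, 49, 51, 60, 64, 72, 89, 104, 114, 116,
)

# Composite (in-frame fusion) gene bookkeeping for the focal genome:
# the alkaline-exonuclease / helicase-2 fusion protein domain layout,
# in amino-acid residues of the composite polypeptide.
FUSION_ALKEXO_HELICASE2 = {
    "total_aa": 886,
    "segments": [("alk-exo", 1, 383), ("helicase-2", 431, 886)],
    "linker_aa": 47,
}
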