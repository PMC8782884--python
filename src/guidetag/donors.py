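"""Published dsODN donor/tag sequences used by GUIDE-seq-family assays.

These are the standard double-stranded oligodeoxynucleotide (dsODN) tags:
the original 34 bp GUIDE-seq donor and the 46 bp iGUIDE variant, given here
as the annotated synthesis strings (5' phosphate or biotin, phosphorothioate
end protection) so that :func:`guidetag.seqio.parse_oligo` can recover the
bare sequences and modification maps.
"""

from .seqio import OligoSpec, parse_oligo

IGUIDE_SENSE_RAW = "5'-P-G*C*TCGCGTTTAATTGAGTTGTCATATGTTAATAACGGTATACGC*G*A"
IGUIDE_ANTISENSE_RAW = "5'-P-T*C*GCGTATACCGTTATTAACATATGACAACTCAATTAAACGCGA*G*C"

GUIDESEQ_SENSE_RAW = "5'-P-G*T*TTAATTGAGTTGTCATATGTTAATAACGGT*A*T"
GUIDESEQ_ANTISENSE_RAW = "5'-P-A*T*ACCGTTATTAACATATGACAACTCAATTAA*A*C"

BIOTIN_IGUIDE_SENSE_RAW = "5'-biotin-G*C*TCGCGTTTAATTGAGTTGTCATATGTTAATAACGGTATACGC*G*A"
BIOTIN_IGUIDE_ANTISENSE_RAW = "5'-biotin-T*C*GCGTATACCGTTATTAACATATGACAACTCAATTAAACGCGA*G*C"

GUIDESEQ_SENSE_INTBIO_RAW = "5'-P-G*T*TTAATTGAGTTGTCAT(biotin)ATGTTAATAACGGT*A*T"
GUIDESEQ_ANTISENSE_INTBIO_RAW = "5'-P-A*T*ACCGTTATTAACATAT(biotin)GACAACTCAATTAA*A*C"


def iguide_duplex() -> tuple[OligoSpec, OligoSpec]:
    """Sense/antisense oligos of the 46 bp iGUIDE dsODN."""
    return parse_oligo(IGUIDE_SENSE_RAW), parse_oligo(IGUIDE_ANTISENSE_RAW)


def guideseq_duplex() -> tuple[OligoSpec, OligoSpec]:
    """Sense/antisense oligos of the 34 bp GUIDE-seq dsODN."""
    return parse_oligo(GUIDESEQ_SENSE_RAW), parse_oligo(GUIDESEQ_ANTISENSE_RAW)
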