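"""Parse the published dsODN donor oligos and check that they anneal.

Synthesis order strings carry chemistry annotations (5' phosphate or
biotin, phosphorothioate bonds); parsing strips them to bare DNA and
records each modification, and the duplex check confirms the two strands
are exact reverse complements.
"""

from guidetag.donors import guideseq_duplex, iguide_duplex
from guidetag.seqio import duplex_check

for name, (sense, antisense) in [("iGUIDE", iguide_duplex()),
                                 ("GUIDE-seq", guideseq_duplex())]:
    d = duplex_check(sense, antisense)
    print(f"{name} donor: {len(sense.clean)} nt strands -> "
          f"{'blunt' if d.blunt else 'overhanging'} duplex of {d.length} bp")
    print(f"  sense 5'->3': {sense.clean}")
    print(f"  modifications: {sense.modifications}")

# The printed lengths (46 bp iGUIDE, 34 bp GUIDE-seq) are the tag sizes the
# insert-viewpoint libraries are anchored on.
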