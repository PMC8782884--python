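"""Search a genomic window for a near-cognate protospacer match.

The discovery-mode matcher tolerates up to 6 mismatches and a single
DNA or RNA bulge, and requires a relaxed NNG-or-NGN PAM 3' of the site.
"""

import numpy as np

from guidetag.discovery import GuideSpec, search_protospacer

rng = np.random.default_rng(0)
spacer = "GACGCATAAAGATGAGACGC"
guide = GuideSpec(spacer=spacer)

# A window holding a 3-mismatch site with an extra genomic base (DNA bulge)
site = spacer[:2] + "TCA" + spacer[5:10] + "G" + spacer[10:]  # 3 mm + bulge
window = ("".join(rng.choice(list("ACGT"), 40)) + site + "AGG"
          + "".join(rng.choice(list("ACGT"), 40)))

hit = search_protospacer(window, guide)
print(f"best match at window[{hit.start}:{hit.end}] on strand {hit.strand}")
print(f"  site sequence : {hit.site_seq}")
print(f"  mismatches    : {hit.mismatches}")
print(f"  bulge         : {hit.bulge}")   # ('DNA', gap) = extra genomic base
print(f"  PAM           : {hit.pam}")

# Mismatch count and bulge placement feed the off-target site table; sites
# beyond 6 mismatches or without a G at PAM position 2 or 3 return None.
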