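"""Find a seed-anchored target site and score the duplex.

Plants the exact reverse complement of a miRNA's nt 2-13 into a synthetic
transcript, recovers it with the scan, folds the miRNA against a window
around the anchor and prints the minimum free energy with its text diagram.
"""

import numpy as np

from xkmir import (
    EnergyParameters,
    MatureMiRNA,
    TranscriptRecord,
    find_sites,
    hybridize,
    make_window,
    passes_criteria,
    plant_site,
)

mirna = MatureMiRNA("zma-miR156a-3p", "zma", "GCUCACUUCUCUCUCUGUCAGU", read_count=5000)
rng = np.random.default_rng(0)
background = "".join(rng.choice(list("ACGU"), size=200))
seq, n_sub = plant_site(background, mirna, position=90, extend_prob=1.0, rng=rng)
transcript = TranscriptRecord("demo.t1", "DEMO", "coding", seq, cds_start=40, cds_end=160)

(site,) = find_sites([mirna], [transcript])
print(f"site: {site.transcript_id}:{site.site_start}-{site.site_end} "
      f"({site.site_sequence})")

window = make_window(transcript, site, len(mirna))
duplex = hybridize(mirna, window, EnergyParameters(),
                   require_seed_wc=True, forbid_seed_gu=True)
print(f"MFE = {duplex.mfe:.1f} kcal/mol; "
      f"passes criteria (< -25): {passes_criteria(duplex)}")
print(duplex.diagram)

# The planted site substituted the full complement of the miRNA (n_sub
# nucleotides), so the duplex pairs end-to-end and the MFE lands well below
# the -25 kcal/mol acceptance threshold.
print(f"substituted nucleotides: {n_sub}")
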