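"""Seed mimicry against host miRNAs and cross-species conservation.

A host miRNA sharing a plant miRNA's nt 2-7 seed can engage the same target
sites; exact full-length duplicates of a mature sequence in other species
indicate evolutionary conservation.
"""

from xkmir import MatureMiRNA, find_conserved, find_seed_mimics
from xkmir.fixtures import pca_mirnas

plant = pca_mirnas()

host = [
    # identical seed (GGAAGG) to zma-miR528a/b-5p
    MatureMiRNA("hsa-miR-demo-1", "hsa", "AGGAAGGCAUCGAUCGAUCGA"),
    MatureMiRNA("hsa-miR-demo-2", "hsa", "UCCCCCGGGAUCGAUCGAUCG"),
]
pairs = find_seed_mimics(plant, host)
print(f"{len(pairs)} seed-identical plant/host pairs:")
for p in pairs:
    print(f"  {p.plant_mirna_id} ~ {p.host_mirna_id} (seed {p.shared_seed})")

catalogue = plant + [
    MatureMiRNA("sbi-miR396", "sbi", "UUCCACAGGCUUUCUUGAACUG"),
    MatureMiRNA("osa-miR167h", "osa", "GAUCAUGUUGCAGCUUCAC"),
]
hits = find_conserved(plant, catalogue)
detected = [h for h in hits if h.detected]
print(f"{len(detected)} of {len(hits)} miRNAs found identically in other species:")
for h in detected:
    print(f"  {h.mirna_id}: {', '.join(sorted(h.matching_species))}")

# Each reported match is an exact, full-length mature-sequence identity;
# one-nucleotide variants never count.
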