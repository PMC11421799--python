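"""Sequence context of pseudouridine sites: motif classes, position
frequencies, codon context and background-site selection.

Builds a synthetic transcriptome with UURAA-planted sites and prints the
motif class of each site, the position-frequency matrix around them (the
recognition motif fixes U at +1 and A at +4), the codons the sites fall in,
and an expression-matched set of unmodified background motif instances.
"""

import psistop as ps
from psistop.motifs import amino_acid_fractions

config = ps.SimulationConfig(
    n_transcripts=8, transcript_length=600, depth=1000,
    planted_sites=[ps.PlantedSite(f"gene{i:03d}", 150 + 17 * i)
                   for i in range(8)],
    seed=4,
)
tr = ps.make_transcriptome(config)
sites = [tr.genomic_site(s) for s in tr.sites]

print("motif class per site:")
for pos, strand in sites:
    print(f"  {pos} ({strand}): {ps.classify_motif(tr.genome, pos, strand)}")

pfm = ps.position_frequency(sites, tr.genome, flank=5)
print("\nposition-frequency matrix (rows: offset from the site U):")
print(pfm.to_string())
print("\nNote the invariant columns: U at offsets 0 and +1, A at +4 — the "
      "planted UURAA recognition motif.")

frac = amino_acid_fractions(sites, tr.models, tr.genome)
print("\namino acids encoded at the modified codons (fraction of sites):")
print(frac.to_string())

for m in tr.models:
    m.rpkm = 200.0  # everything "well expressed" for this toy example
background = ps.select_background(tr.models, tr.genome, sites,
                                  rpkm_min=105.0, exclusion_nt=100)
print(f"\n{len(background)} background UURAA instances selected (same "
      "motif, well-expressed genes, >100 nt from any called site).")
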