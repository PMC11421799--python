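"""Assign called sites to pseudouridine synthases using knockout libraries.

Simulates wild-type CMC/mock libraries plus CMC libraries for three synthase
knockouts, then checks, for each called site, in which knockout the peak
disappears (knockout Z < 10 and wild-type Z at least 4-fold higher, with
sufficient knockout coverage).  A site absent in exactly one covered
knockout is assigned to that enzyme.
"""

import psistop as ps

config = ps.SimulationConfig(
    n_transcripts=6, transcript_length=800, depth=250_000,
    planted_sites=[
        ps.PlantedSite("gene000", 400, enzyme="rluA"),
        ps.PlantedSite("gene002", 250, enzyme="rluD"),
        ps.PlantedSite("gene004", 600, enzyme="truB"),
    ],
    seed=23,
)
transcriptome = ps.make_transcriptome(config)
knockouts = ["rluA", "rluD", "truB"]
tracks = ps.simulate_pseudoseq_suite(config, transcriptome,
                                     knockouts=knockouts)

labels = {e: f"d{e}-CMC" for e in knockouts}
calls = ps.scan_transcriptome(tracks, transcriptome.genome,
                              transcriptome.models,
                              extra_labels=list(labels.values()))
results = ps.assign_sites(calls, ko_labels=labels)

print(f"{'position':>9} {'gene':>9} {'status':>10} {'enzyme':>8} "
      f"{'absent in':>20}")
for r in results:
    print(f"{r.site.position:>9} {r.site.gene_id:>9} {r.status:>10} "
          f"{r.enzyme or '-':>8} {','.join(r.absent_in) or '-':>20}")

print("\nEach site's assigned enzyme should equal the planted one; the "
      "peak survives in the other knockouts, so the absence is specific.")
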