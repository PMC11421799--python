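# psistop

Pseudouridine (Ψ) site discovery from CMC reverse-transcription-stop
sequencing (Pseudo-Seq), for bacterial transcriptomes.

Ψ cannot be read out by sequencing directly, but the carbodiimide CMC forms
an adduct on Ψ that survives alkaline treatment and blocks reverse
transcriptase one nucleotide downstream of the modified uridine.  Comparing
per-position read 5′-end counts between a CMC-treated library and a
mock-treated control therefore reveals Ψ sites as CMC-dependent pileups.
`psistop` implements the full downstream analysis for such data — it starts
from per-position, per-strand 5′-end count tracks (wiggle/bedGraph) and a
transcript annotation, and produces called sites, enzyme assignments,
saturation curves, and sequence/structure context profiles.  A synthetic
RT-stop library generator with planted ground truth makes every stage
verifiable without external data.

## The statistic

For each uridine *u* the caller scores the RT-stop position *u*+1 against a
100-nt background window surrounding it:

```
Z(u) = ( n[u+1] − mean(winsorized background) ) / sd(winsorized background)
```

where the background is 95%-winsorized (values above the 95th percentile are
capped at it; the target itself is never altered) and the sd uses the
population (divide-by-*n*) form.  Windows must carry ≥ 100 reads, and windows
near transcript boundaries are shifted to stay ≥ 40 nt downstream of the
nearest upstream 5′ end, ≥ 5 nt downstream of an upstream 3′ end, ≥ 25 nt
upstream of a downstream 3′ end and ≥ 5 nt upstream of a downstream 5′ end
(Rend-Seq end annotations drive this).  A site is called when

* Z(CMC) ≥ 15, and
* Z(CMC) ≥ 3 × Z(mock),

and it is attributed to a pseudouridine synthase when, in exactly one of the
knockout libraries, the peak is *absent*: knockout window covered,
Z(knockout) < 10, and Z(CMC) ≥ 4 × Z(knockout).  Absence in two or more
knockouts is `ambiguous`; a missing knockout coverage leaves the site
`unassigned`.

## Worked example

`examples/simulate_and_call.py` simulates a 6-transcript study with three
planted Ψ sites (known enzyme and stop efficiency) and calls sites at the
default thresholds:

```
scanned 1166 uridines, called 3 sites

 position strand      gene    Z(CMC)   Z(mock)
      600      +   gene000    1986.1      1.50
     2749      -   gene002    2108.7      0.76
     4399      -   gene004    1995.4      0.12

planted truth:
gene_id  u_position strand enzyme
gene000         600      +   rluA
gene002        2749      -   rluD
gene004        4399      -   rluA
```

Every called position coincides with a planted U (the caller reports the
modified U, not the U+1 stop position), Z-scores in the CMC library are three
orders of magnitude above mock, and no unplanted uridine is called.  The
other scripts in `examples/` walk through enzyme assignment, saturation
analysis, sequence context (motif classes, position-frequency matrices,
codon usage, background-site selection), reactivity-constrained structure
context, and targeted-bisulfite (BID-seq) validation.

A `psistop` command-line entry point wraps the same library surface
(`psistop simulate|call|assign|saturate|motif|background|structure|bidseq|run`),
with `psistop run --config demo.yaml` driving the full pipeline from a single
YAML file and writing a reproducibility manifest.

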