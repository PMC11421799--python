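# Demo pipeline configuration: simulate a small study (seed 1), call sites,
# assign enzymes from two knockout libraries, and quantify BID-seq signal.
# Run with:  psistop run --config examples/demo.yaml
seed: 1
outdir: demo_out
window_len: 100
thresholds:
  z_min: 15
  mock_fold: 3
  coverage_min: 100
  ko_z_max: 10
  ko_fold: 4
simulate:
  n_transcripts: 5
  transcript_length: 700
  depth: 150000
  expression_sigma: 0.3
  knockouts: [rluA, rluD]
  sites:
    - {gene: gene001, u: 350, enzyme: rluA}
    - {gene: gene003, u: 200, enzyme: rluD}
bidseq:
  depth: 5000
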