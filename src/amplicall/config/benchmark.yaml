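# Pipeline configuration mirroring the packaged six-sample benchmark:
# the default duplicated locus, default nanopore-like error model with five
# strand-biased recurrent transition hotspots, and eight planted true
# variants.  `amplicall run --config` accepts this file.
reference:
  span: 8911
  n_exons: 11
  exon_len: 170
  exon_identity: 96.0
  intron_identity: 97.0
  seed: 0

error_model:
  # calibrated so ABID ~ 93.2% and the G>A / A>G / C>T spectrum shares
  # land at their observed run values
  sub_rate: 0.0672
  homopolymer_indel_rate: 0.02
  chimera_rate: 0.02
  min_read_len: 2000
  motif: CAGC
  motif_factor: 4.0

systematic_sites:
  # position fractions of the span; realized per-sample aberrant fractions
  # are drawn in [0.14, 0.30]; all are transitions with 3:1 strand bias
  position_fractions: [0.10, 0.27, 0.44, 0.64, 0.81]
  fraction_range: [0.14, 0.30]
  strand_ratio: 3.0

samples:
  depth: 140
  n_samples: 6

filter:
  preset: default        # adjusted-score thresholds 1.8 / 1.2
  recur_min: 0.10
  anchor: 3.5            # calibration anchor for true-het mean adjusted score

gates:
  coverage_gate: 100
  flank: 50
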