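# Default pipeline configuration: the canonical synthetic locus.
# "locus: default" expands to a 900-kb span with a divergent pair of CTCF
# arrays at the transition zone (450-520 kb), four viewpoints, and the
# engineered-allele series (Hap, del1-3, del-L/R, inv-L/R).
seed: 0
workdir: tz4c_out
locus: default
sim:
  alpha: 1.0          # distance-decay exponent
  d0: 2000            # decay offset, bp
  read_depth: 200000  # reads per library
  n_replicates: 3
annotation:
  n_datasets: 31      # synthetic ChIP datasets
  k: 14               # consensus support threshold
  scan_window: 200    # bp, centered on peak midpoint
  fold_threshold: 3.0 # CTCF/IgG fold for 'direct'
  jitter_sd: 25
  peak_halfwidth: 150
  noise_rate: 2.0
processing:
  smooth_window: 11   # fragments
  rpm: true
stats:
  directionality_window: 200000  # bp each side of the viewpoint
  reference_allele: Hap
  alternative: greater
proportions_viewpoint: VP-Tfap2c
log_level: INFO
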