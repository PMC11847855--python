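genome:
  chrom_lengths:
  - 115.28742514970061
  - 89.56946107784431
  - 85.13532934131737
  - 83.36167664670658
  - 77.15389221556886
  - 71.83293413173654
  - 70.05928143712575
  - 66.5119760479042
  - 65.6251497005988
  - 62.964670658682635
  - 60.304191616766474
  - 40.79401197604791
  n_marker_loci: 30000
  n_qtl_loci: 25000
  qtl_alleles: 2
  Ne: 200
  n_hist_generations: 1000
  bottleneck:
  - 901
  - 950
  - 100
  maf_min: 0.05
  n_markers: 2000
  n_qtl: 2000
trait:
  sigma_a2: 1.0
  sigma_d2: 0.0
  sigma_aa2: 0.0
  sigma_ad2: 0.0
  sigma_dd2: 0.0
  sigma_e2: 2.0
  dominance_degree:
  - 0.19
  - 0.097
  rescale_method: by_locus
scheme:
  n_parents: 80
  n_families: 80
  family_size: 10
  max_contrib: 4
  no_selfing: true
  n_generations: 13
  random_selection_until: 5
  reml_at_generation: 6
  selection_model: additive
  ploidy: 2
  allelism_profile:
  - - 2
    - 1.0
  n_ep: 0
  n_founders: 100
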