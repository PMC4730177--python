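# Demo run: a scaled-down two-soil contrast with realistic 454-style
# error rates. Outputs land in the directory passed to `nifscape run --out`.
seed: 7
n_taxa: 24
divergence: 0.15
habitats:
  - name: desert_soil
    richness: 6
    depth_range: [700, 900]
    lognormal_sigma: 2.0
  - name: field_soil
    richness: 14
    depth_range: [700, 900]
    lognormal_sigma: 1.2
substitution_rate: 0.001
indel_rate: 0.05
min_mean_q: 20
min_len: 200
normalize_depth: 500
cutoffs: [0.0, 0.04, 0.08]
n_perm: 1000
bootstrap_reps: 100
max_tree_otus: 30
qpcr_log10_copies:
  desert_soil: 4.4
  field_soil: 6.0
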