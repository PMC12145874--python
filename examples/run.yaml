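# Demonstration pipeline configuration: 4 strains x 3 pH conditions,
# 1200-gene universe, 60 simulated sets plus GO-style sets from a toy
# ontology, all three pairwise pH contrasts.
seed: 1
out_dir: phresp_demo
n_strains: 4
n_wells: 6
n_periods: 4
period_length: 3.0
noise_cv: 0.05
n_genes: 1200
n_sets: 60
set_size_range: [8, 25]
frac_enriched_sets: 0.08
frac_depleted_sets: 0.08
deg_rate_null: 0.02
effect_deg_rate: 0.8
effect_unidirectional: true
share_frac: 0.8
n_ontology_terms: 30
contrasts:
  - ["4.7", "8.2"]
  - ["4.7", "7.0"]
  - ["7.0", "8.2"]
deg_alpha: 0.01
growth_alpha: 0.05
enrich_alpha: 0.01
ugs_min_degs: 2
n_perm: 1000
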