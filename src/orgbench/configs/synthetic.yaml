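# Bundled synthetic benchmark configuration.
#
# Four scenarios are simulated, each tuned for the check it feeds:
# - network_scenario: 5 planted modules x 150 genes, 10 stages x 4 samples;
#   a strong per-(module,sample) random effect keeps the trend-free "flat"
#   module detectable by co-expression alone.
# - warp_scenario: fine reference stage grid and low module noise so the
#   time-warp factor is identifiable from per-sample stage best-matches.
# - dea_scenario: linear day grid and strong loadings so consecutive-stage
#   fold changes clear the |log2FC| > 1 DEG threshold at tau = 1.
# - deconv_scenario: 3-type single-cell reference and 20 bulk mixtures.
seed: 1
outdir: scratch/synthetic_run

simulate:
  network_scenario:
    n_genes: 1000
    n_modules: 5
    genes_per_module: 150
    n_stages: 10
    samples_per_stage: 4
    module_effect_sd: 0.35
    flat_module_effect_sd: 1.2
  warp_scenario:
    n_ref_stages: 14
    ref_samples_per_stage: 4
    n_days: 10
    day_samples_per_stage: 6
    taus: [0.5, 1.0, 2.0]
    module_effect_sd: 0.1
    flat_module_effect_sd: 0.3
  dea_scenario:
    n_days: 6
    samples_per_stage: 4
    taus: [1.0, 2.0]
    module_effect_sd: 0.1
    flat_module_effect_sd: 0.15
    loading_min: 2.5
    loading_max: 3.5
  deconv_scenario:
    n_types: 3
    cells_per_type: 300
    n_mixtures: 20

network:
  beta: 18
  deep_split: 1
  min_cluster_size: 50
  pam_stage: true
  cut_height: 0.97
  hub_top_n: 20
  hub_min_edge: 0.2

dea:
  fdr: 0.05
  min_abs_lfc: 1.0
  min_cpm: 2.0
  min_samples: 4

overlap:
  or_min: 3.0
  p_max: 0.01

go:
  p_max: 0.01
  enrichment_min: 1.75
  min_term_size: 15

deconv:
  qc: 0.65

benchmark:
  min_shared_genes: 500
  pca_top_k: 100

calibration:
  n_genes: 1500
  n_per_group: 4
  phi: 0.1
  fold: 4.0
  frac_de: 0.1
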