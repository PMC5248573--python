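# Named generator presets. Fate presets encode the published cohort
# behavior of each line under 1 uM vemurafenib or DMSO; the rest are
# plumbing presets for plate, expression, screen, biopsy and outgrowth
# generators.

fate:
  colo858_vem:
    p_death: 0.60
    p_arrest: 0.20
    p_adapt: 0.20
    death_window_h: [24.0, 48.0]
    reentry_window_h: [48.0, 80.0]
    intermitotic_mean_h: 65.0
    intermitotic_cv: 0.15
    s_g2_duration_h: 10.0
    untreated_doubling_h: 24.0
    noise_sd: 0.3
    sampling_interval_min: 6.0
    movie_length_h: 84.0
  mmacsf_vem:
    p_death: 0.40
    p_arrest: 0.60
    p_adapt: 0.0
    death_window_h: [24.0, 48.0]
    reentry_window_h: [48.0, 80.0]
    intermitotic_mean_h: 65.0
    intermitotic_cv: 0.15
    s_g2_duration_h: 10.0
    untreated_doubling_h: 24.0
    noise_sd: 0.3
    sampling_interval_min: 6.0
    movie_length_h: 84.0
  colo858_dmso:
    p_death: 0.0
    p_arrest: 0.0
    p_adapt: 1.0
    death_window_h: [24.0, 48.0]
    reentry_window_h: [48.0, 80.0]
    intermitotic_mean_h: 65.0
    intermitotic_cv: 0.10
    s_g2_duration_h: 10.0
    untreated_doubling_h: 24.0
    noise_sd: 0.3
    sampling_interval_min: 6.0
    movie_length_h: 84.0

plate:
  colo858_seq:
    doses: [0.0, 0.01, 0.032, 0.1, 0.32]
    true_ec50: 0.2
    true_hill: 2.0
    true_emax: 0.10
    initial_count: 2500
    control_doublings: 2.0
    apoptosis_background: 0.05
    replicate_cv: 0.05
    n_replicates: 4
    protection_fold: 2.5
    protection_peak_um: 0.1
    protection_width_log10: 0.5
  mmacsf_seq:
    doses: [0.0, 0.01, 0.032, 0.1, 0.32]
    true_ec50: 0.2
    true_hill: 2.0
    true_emax: 0.05
    initial_count: 2500
    control_doublings: 2.0
    apoptosis_background: 0.05
    replicate_cv: 0.05
    n_replicates: 4
    protection_fold: 1.0
  colo858_dr:
    doses: [0.0, 0.0032, 0.01, 0.032, 0.1, 0.32, 1.0, 3.2]
    true_ec50: 0.2
    true_hill: 2.0
    true_emax: 0.10
    initial_count: 2500
    control_doublings: 2.0
    apoptosis_background: 0.05
    replicate_cv: 0.05
    n_replicates: 4

expression:
  default:
    n_genes: 1000
    n_planted_up: 50
    n_planted_down: 50
    planted_log2ratio: 2.0
    fpkm_floor: 1.0
    q_signal: 0.001
    q_null: 0.5
    dispersion: 0.05

screen:
  default:
    n_compounds: 41
    n_doses: 3
    n_lines: 3
    suppressor_ids: [7, 19, 33]
    suppression_log2: 1.5
    noise_sd: 0.15
    n_replicates: 2
    doses_um: [0.11, 0.53, 2.67]

biopsy:
  on_treatment:
    n_cells: 10000
    frac_marker_high: {ngfr: 0.30, ki67: 0.40}
    high_low_separation: 2.5
    background_frac: 0.05
    background_boost: 3.0
  pretreatment:
    n_cells: 10000
    frac_marker_high: {ngfr: 0.07, ki67: 0.80}
    high_low_separation: 2.5
    background_frac: 0.05
    background_boost: 3.0

growth:
  ngfr_high_pool:
    doubling_h: 32.0
    initial_count: 1000
    n_replicates: 4
    replicate_cv: 0.05
  ngfr_low_pool:
    doubling_h: 18.0
    initial_count: 1000
    n_replicates: 4
    replicate_cv: 0.05
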