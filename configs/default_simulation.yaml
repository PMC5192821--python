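# Calibrated generator defaults (see analysis/05_calibrate_generator.py
# and docs/methods.md); usable via `phet simulate --config ...`.
n_plots: 39
n_soil_replicates: 4
pool_size: 156
stems_range:
- 84
- 300
scenario: niche_coupled
an_mean_range:
- 123.25
- 240.25
an_cv_range:
- 0.02
- 0.35
ep_mean_range:
- 2.43
- 23.4
ep_cv_range:
- 0.16
- 1.13
couple_mean_cv: false
mean_cv_rho: 0.6
niche_breadth: 0.25
n_microniches: 8
microniche_spread_base: 0.45
microniche_spread_scale: 0.9
plot_center_sd: 0.5
clade_filter_strength: 12.0
relatedness_filter_strength: 4.0
cv_pivot: 0.55
repulsion_scale: 1.2
max_repulsion_retries: 20
immigration: 0.06
unimodal_penalty: 0.8
lottery_sigma: 1.0
sad_sigma: 1.5
dispersal_sigma: 1.5
dbh_log_median: 4.0
dbh_log_sigma: 0.7
dbh_min: 1.0
seed: 0
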