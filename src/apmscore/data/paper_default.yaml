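# Paper-default synthetic cohort configuration.
#
# Distributional targets are the printed cohort statistics: APM median 15
# (IQR 12-17, clip 6-21 mm); APACHE II median 15 (IQR 12-20); APACHE III
# median 47 (IQR 33-66); mortality 31.57%; age 54.75 +/- 18.28; 61.5% male;
# albumin 3.19 +/- 0.72; subtype medical/surgical/trauma from the overall
# column.  The conditional outcome coefficients were produced once by
# apmscore.simulate.calibrate_generator (pilot n=400000, seed 20180603) so
# that the observable univariate quantities match their printed values:
# per-point APACHE II OR 1.20; death-probability curve crossing 0.5 at 10 mm
# (hinge default); per-mm APM OR 0.623 (linear variant).
config:
  n: 304
  seed: null
  apm:
    mean: 15.0
    sd: 4.0
    clip: [6.0, 21.0]
    integer: true
    reading_noise_sd: 0.3
  apache2: {median: 15, q1: 12, q3: 20, clip: [0, 71]}
  apache3: {median: 47, q1: 33, q3: 66, clip: [0, 299]}
  apache_rank_corr: 0.8
  outcome:
    target_mortality: 0.3157
    intercept: null
    apm_effect: hinge
    beta_apm: 0.403181
    beta_apache2: 0.211252
    pilot_n: 200000
  covariates:
    male_frac: 0.615
    age_mean: 54.75
    age_sd: 18.28
    albumin_mean: 3.19
    albumin_sd: 0.72
    subtype_probs: {medical: 0.092, surgical: 0.609, trauma: 0.299}
  gcs_kappa: 0.33
  gcs_noise_sd: 1.5
  n_nuisance: 0
  nuisance_loading: 0.3
linear_variant:
  beta_apm: 0.645634
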