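# Cohort presets for synthetic macrophage force-volume cohorts.
#
# provenance tags per quantity:
#   printed      - value printed in the source study
#   fold-printed - derived from a printed fold change and an assumed anchor
#   assumed      - declared package assumption (no printed value exists)
#
# Modulus scale distributions are lognormal with the stated linear-space
# mean/sd (kPa); the power-law exponent is a truncated normal on [0, 1];
# apex heights are lognormal with the stated mean (um) and CV.
version: 1
defaults:
  n_cells: 20
  grid_n: 16
  field_um: 30.0
  base_radius_um: 10.0
  height_cv: 0.05
  alpha_sd: 0.05
  eta_pa_s: 0.0
presets:
  M1_control:
    e1_mean_kpa: 2.8        # printed
    e1_sd_kpa: 1.09         # printed
    alpha_mean: 0.25        # assumed (only the direction of change is printed)
    height_mean_um: 4.0     # assumed anchor
  M1_PMA:
    e1_mean_kpa: 6.92       # printed
    e1_sd_kpa: 2.87         # printed
    alpha_mean: 0.15        # assumed
    height_mean_um: 2.6144  # fold-printed: 4.0 / 1.53
  M2_control:
    e1_mean_kpa: 3.0        # assumed
    e1_sd_kpa: 1.2          # assumed
    alpha_mean: 0.25        # assumed
    height_mean_um: 4.0     # assumed anchor
  M2_PMA:
    e1_mean_kpa: 5.0        # assumed
    e1_sd_kpa: 2.0          # assumed
    alpha_mean: 0.15        # assumed
    height_mean_um: 2.3669  # fold-printed: 4.0 / 1.69
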