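# Reference-cohort synthetic preset: three cranial categories with the standard
# 31-landmark schema, modular-but-integrated covariance, directional and
# fluctuating asymmetry. Variances are mm^2 along unit loading fields.
schema: cranial31
n_per_group:
  antero-posterior: 74
  non-deformed: 118
  oblique: 77
# symmetric (static) integration: rho = 34 / (34 + 6) = 0.85
integration_strength: 34.0
within_module_variance:
  viscerocranium: 6.0
  neurocranium: 6.0
# asymmetric (developmental) integration: rho = 3.4 / (3.4 + 0.6) = 0.85
fa_integration_strength: 3.4
fa_module_variance: 0.6
fa_variance: 0.8
da_scale: 1.5
ap_compression: 0.08
oblique_shear: 0.08
deformation_sd_frac: 0.5
measurement_error_sd: 0.3
residual_sd: 0.5
n_replicates: 1
seed: 0
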