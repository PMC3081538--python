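{
  "profiles": [
    {"name": "pfam_domain", "tpr": 0.62, "fpr": 0.01, "coverage": 1.0, "correlation_group": "pfam", "noise_sd": 0.05, "role": "strong"},
    {"name": "targetp", "tpr": 0.55, "fpr": 0.012, "coverage": 1.0, "correlation_group": null, "noise_sd": 0.05, "role": "strong"},
    {"name": "mitopred", "tpr": 0.68, "fpr": 0.01, "coverage": 1.0, "correlation_group": "pfam", "noise_sd": 0.05, "role": "strong"},
    {"name": "cis_motif", "tpr": 0.30, "fpr": 0.05, "coverage": 0.95, "correlation_group": null, "noise_sd": 0.05, "role": "moderate"},
    {"name": "msms_mouse", "tpr": 0.32, "fpr": 0.04, "coverage": 0.9, "correlation_group": null, "noise_sd": 0.05, "role": "moderate"},
    {"name": "mitoprot", "tpr": 0.35, "fpr": 0.06, "coverage": 1.0, "correlation_group": null, "noise_sd": 0.05, "role": "moderate"},
    {"name": "subloc", "tpr": 0.28, "fpr": 0.05, "coverage": 1.0, "correlation_group": null, "noise_sd": 0.05, "role": "moderate"},
    {"name": "yeast_homology", "tpr": 0.08, "fpr": 0.08, "coverage": 0.25, "correlation_group": null, "noise_sd": 0.45, "role": "detrimental"},
    {"name": "pgc1a_induction", "tpr": 0.08, "fpr": 0.08, "coverage": 0.3, "correlation_group": null, "noise_sd": 0.45, "role": "detrimental"},
    {"name": "rprowazekii_orthology", "tpr": 0.05, "fpr": 0.05, "coverage": 0.2, "correlation_group": null, "noise_sd": 0.45, "role": "detrimental"},
    {"name": "coexpression", "tpr": 0.1, "fpr": 0.1, "coverage": 0.3, "correlation_group": null, "noise_sd": 0.45, "role": "detrimental"}
  ],
  "n_pos": 467,
  "n_neg": 6352,
  "latent_strength": 0.4,
  "seed": 0
}
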