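{
  "life_table": {
    "female": {
      "level": 1e-05,
      "makeham": 0.0002,
      "slope": 0.105
    },
    "male": {
      "level": 2.5e-05,
      "makeham": 0.0003,
      "slope": 0.1
    },
    "max_age": 100
  },
  "notes": "Parameters tagged 'synthetic' are generated stand-ins of plausible magnitude, not published values.",
  "provenance": {
    "ae_episode_costs.hepatitis_b": "paper",
    "ae_episode_costs.herpes_zoster": "paper",
    "ae_episode_costs.pneumonia": "paper",
    "ae_episode_costs.tuberculosis": "paper",
    "first_line.biosimilar_adalimumab.acr_response": "paper",
    "first_line.biosimilar_adalimumab.ae_probs.hepatitis_b": "paper",
    "first_line.biosimilar_adalimumab.ae_probs.herpes_zoster": "paper",
    "first_line.biosimilar_adalimumab.ae_probs.pneumonia": "paper",
    "first_line.biosimilar_adalimumab.ae_probs.tuberculosis": "paper",
    "first_line.biosimilar_adalimumab.discontinuation_prob": "paper",
    "first_line.biosimilar_adalimumab.drug_cost_first_cycle": "paper",
    "first_line.biosimilar_adalimumab.drug_cost_subsequent": "paper",
    "first_line.biosimilar_infliximab.acr_response": "paper",
    "first_line.biosimilar_infliximab.ae_probs.hepatitis_b": "paper",
    "first_line.biosimilar_infliximab.ae_probs.herpes_zoster": "paper",
    "first_line.biosimilar_infliximab.ae_probs.pneumonia": "paper",
    "first_line.biosimilar_infliximab.ae_probs.tuberculosis": "paper",
    "first_line.biosimilar_infliximab.discontinuation_prob": "paper",
    "first_line.biosimilar_infliximab.drug_cost_first_cycle": "paper",
    "first_line.biosimilar_infliximab.drug_cost_subsequent": "paper",
    "first_line.leflunomide.acr_response": "paper",
    "first_line.leflunomide.discontinuation_prob": "paper",
    "first_line.leflunomide.drug_cost_first_cycle": "paper",
    "first_line.leflunomide.drug_cost_subsequent": "paper",
    "first_line_haq_changes.acr20_50": "paper",
    "first_line_haq_changes.acr50_70": "paper",
    "first_line_haq_changes.ge70": "paper",
    "first_line_haq_changes.lt20": "paper",
    "pooled_jaki.ae_probs.hepatitis_b": "synthetic",
    "pooled_jaki.ae_probs.herpes_zoster": "synthetic",
    "pooled_jaki.ae_probs.pneumonia": "synthetic",
    "pooled_jaki.ae_probs.tuberculosis": "synthetic",
    "pooled_jaki.discontinuation_prob": "synthetic",
    "pooled_jaki.drug_cost_first_cycle": "synthetic",
    "pooled_jaki.drug_cost_subsequent": "synthetic",
    "pooled_jaki.haq_change_mean": "synthetic",
    "pooled_non_tnfi.ae_probs.hepatitis_b": "synthetic",
    "pooled_non_tnfi.ae_probs.herpes_zoster": "synthetic",
    "pooled_non_tnfi.ae_probs.pneumonia": "synthetic",
    "pooled_non_tnfi.ae_probs.tuberculosis": "synthetic",
    "pooled_non_tnfi.discontinuation_prob": "synthetic",
    "pooled_non_tnfi.drug_cost_first_cycle": "synthetic",
    "pooled_non_tnfi.drug_cost_subsequent": "synthetic",
    "pooled_non_tnfi.haq_change_mean": "synthetic",
    "pooled_tnfi.ae_probs.hepatitis_b": "synthetic",
    "pooled_tnfi.ae_probs.herpes_zoster": "synthetic",
    "pooled_tnfi.ae_probs.pneumonia": "synthetic",
    "pooled_tnfi.ae_probs.tuberculosis": "synthetic",
    "pooled_tnfi.discontinuation_prob": "synthetic",
    "pooled_tnfi.drug_cost_first_cycle": "synthetic",
    "pooled_tnfi.drug_cost_subsequent": "synthetic",
    "pooled_tnfi.haq_change_experienced": "synthetic",
    "pooled_tnfi.haq_change_mean": "synthetic",
    "population.baseline_haq": "paper",
    "supportive_care.drug_cost_per_cycle": "synthetic",
    "supportive_care.physiotherapy_cost_per_cycle": "synthetic",
    "supportive_care.steroid_injection_cost": "synthetic"
  },
  "seed": 20240614
}
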