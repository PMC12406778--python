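{
  "description": "Measured per-method token averages and call volumes from the DRC vaccination-survey free-text categorization campaign (9865 unique strings; 200 clusters for the cluster-labeling strategy), with September-2024 API prices.",
  "pricing": {
    "input_per_million": 2.5,
    "output_per_million": 10.0,
    "embedding_per_million": 0.02,
    "training_per_million": 25.0
  },
  "methods": [
    {"method": "cluster_label_gmm_200", "n_calls": 200, "avg_prompt_tokens": 605, "avg_completion_tokens": 1, "upfront": 0.0003},
    {"method": "zero_shot", "n_calls": 9865, "avg_prompt_tokens": 398, "avg_completion_tokens": 1, "upfront": 0},
    {"method": "chain_of_thought", "n_calls": 9865, "avg_prompt_tokens": 472, "avg_completion_tokens": 52, "upfront": 0},
    {"method": "few_shot_20", "n_calls": 9865, "avg_prompt_tokens": 621, "avg_completion_tokens": 1, "upfront": 0},
    {"method": "few_shot_50", "n_calls": 9865, "avg_prompt_tokens": 943, "avg_completion_tokens": 1, "upfront": 0},
    {"method": "few_shot_400", "n_calls": 9865, "avg_prompt_tokens": 4486, "avg_completion_tokens": 1, "upfront": 0},
    {"method": "few_shot_799", "n_calls": 9865, "avg_prompt_tokens": 8464, "avg_completion_tokens": 1, "upfront": 0},
    {"method": "fine_tuned_799", "n_calls": 9865, "avg_prompt_tokens": 398, "avg_completion_tokens": 1, "upfront": 13}
  ]
}
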