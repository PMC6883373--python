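{
  "seed": 11,
  "outdir": "maizegs_out",
  "trait": "GY",
  "simulate": {
    "n_populations": 3,
    "lines_per_population": [40, 40, 40],
    "n_chromosomes": 5,
    "markers_per_chromosome": 60,
    "n_qtl": 50,
    "environments": [["WW1", "WW"], ["WW2", "WW"], ["WS1", "WS"]],
    "blocks_per_rep": 5,
    "n_checks": 4
  },
  "stage2": {
    "capacity_per_cohort": 20,
    "environments": [["WW1", "WW"], ["WW2", "WW"], ["WS1", "WS"]],
    "blocks_per_rep": 5
  },
  "cv_folds": 5,
  "cv_repeats": 2,
  "chain": {"n_iter": 1500, "burn_in": 500, "thin": 2},
  "selection_fraction": 0.15,
  "train_fraction": 0.5
}
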