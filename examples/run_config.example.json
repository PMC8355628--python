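{
  "alpha": 10.0,
  "beta": 0.5,
  "beta_basis": "reads",
  "drift_frac": 0.05,
  "k": 11,
  "max_dist": 10,
  "max_palindrome_frac": 0.5,
  "max_skip": null,
  "max_unexplained_frac": 0.3,
  "min_identity": 0.8,
  "min_qual": 10,
  "min_reads": 3,
  "n_haplotypes": 2,
  "pcr_chimera_frac": 0.05,
  "phase_window": 25,
  "seed": 0,
  "total_copies": 4,
  "vaf_tol": 0.08
}
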