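# Surrogate default parameters for the euchromatin microemulsion lattice
# model.  Rates in 1/s, mismatch costs in k_BT.  These values are
# calibration surrogates chosen once so that the model reproduces the
# reference regimes (uniform dispersion / microphase / phase separation)
# and the inhibitor-response directions at the 50x50 and 100x100 lattice
# scales; override any of them from your own config file.
rates:
  k_chrom_on: 0.0125      # inactive -> active chromatin (on permissive chains)
  k_chrom_off: 0.0375     # active -> inactive (~25% of permissive chromatin active)
  k_rna_prod: 0.1         # transcript production at an active chromatin site
  k_rna_transfer: 0.1     # transcript hand-off chromatin -> neighboring RBP
  k_rna_decay: 0.0002     # per-transcript decay (lifetime ~83 min)
  k_chain_on: 0.005       # chain switches restrictive -> permissive
  k_chain_off: 0.005      # chain switches permissive -> restrictive
  rna_decay_on_chromatin: true
energy:
  w_inactive_boundRBP: 0.6  # inactive chromatin | RNA-bound RBP
  w_inactive_active: 0.6    # inactive chromatin | active chromatin
  w_active_active: 0.6      # active chromatin | active chromatin
  acceptance: metropolis
schedule:
  sweeps_per_interval: 50   # swap sweeps (width*height attempts) per dt_chem
  fallback_dt: 1.0          # bookkeeping clock when all rates are zero (s)
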