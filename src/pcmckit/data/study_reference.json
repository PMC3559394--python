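{
  "description": "Published summary tallies from the Lola ya Bonobo sanctuary post-conflict study (two semi-free-ranging groups, May-August 2011). Used as fixture metadata for consistency checks and as default study conditions for the synthetic colony.",
  "n_conflicts_recorded": 356,
  "n_pairs_analyzed": 346,
  "pc_outcome_counts": {
    "consolation_only": 146,
    "reconciliation_only": 34,
    "consolation_and_reconciliation": 56,
    "no_affiliation": 110
  },
  "observation_hours": {"g1": 301, "g2": 152},
  "scan_counts": {"g1": 794, "g2": 411},
  "n_focal_victims": 32,
  "victim_class_shares": {"adolescent_M": 0.331, "juvenile_F": 0.325},
  "aggressor_class_shares": {"adult_F": 0.512, "adult_M": 0.254},
  "intensity_shares": [0.142, 0.025, 0.34, 0.32, 0.125, 0.041],
  "scratch_rate_bouts_per_min": {"mc": 0.37, "pc_no_affiliation": 0.43, "pc_consolation": 0.19},
  "groom_s_per_min": {"mc": 3.88, "pc_no_affiliation": 2.9, "pc_consolation": 1.98}
}
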