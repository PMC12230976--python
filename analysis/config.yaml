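# Study configuration for the numbered analysis scripts.
# Default generator conditions: 21 birth regions, follow-up 1970-2018,
# census observation 1970/75/80/85 then annual 1987-2018, cohorts 1905-1998.
seed: 20260930
n_individuals: 60000
status_detail: coarse     # headline stayer/leaver/returnee comparison
causes: true              # cause-specific fits feed the decomposition
n_draws: 500
gap_from_ages: [20, 50, 80]
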