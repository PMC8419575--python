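# Northern Hemisphere breeding populations, grouped by ocean basin and
# ordered west to east within each basin. Male abundances.
#
# status: ESTIMATED PLACEHOLDERS. Bottleneck and carrying-capacity values
# are rough editable stand-ins (current-abundance surveys are the only
# well constrained figure); replace with better estimates as available.
# The Arabian Sea non-migratory population is excluded.
status: estimated
oceans:
  pacific: [WP, HI, MX, CA]
  atlantic: [CB, CV]
populations:
  WP: {N_min: 100, N_2015: 600,  N_K: 1500}
  HI: {N_min: 300, N_2015: 5000, N_K: 8000}
  MX: {N_min: 200, N_2015: 3000, N_K: 5500}
  CA: {N_min: 50,  N_2015: 400,  N_K: 1000}
  CB: {N_min: 400, N_2015: 6000, N_K: 9000}
  CV: {N_min: 30,  N_2015: 150,  N_K: 400}
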