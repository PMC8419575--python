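# Southern Hemisphere breeding populations, west-to-east circular order.
# Male abundances (total estimates divided by 2): N_min at the 1960
# whaling bottleneck, N_2015 at the end of the 50-year growth window,
# N_K carrying capacity.
#
# status: ESTIMATED PLACEHOLDERS. The published supplementary abundance
# table is not reproduced here; these values are editable round-number
# stand-ins chosen so that the South Pacific sizes decrease from west to
# east (west Australia and east Australia large, Oceania small), which is
# the feature driving the direction of song revolutions. Replace with the
# supplementary-table values for quantitative reproduction.
status: estimated
populations:
  BR:  {N_min: 250, N_2015: 8000,  N_K: 12000}
  GA:  {N_min: 300, N_2015: 9000,  N_K: 13000}
  MZ:  {N_min: 300, N_2015: 7000,  N_K: 11000}
  MD:  {N_min: 300, N_2015: 7000,  N_K: 11000}
  WA:  {N_min: 300, N_2015: 14000, N_K: 18000}
  EA:  {N_min: 150, N_2015: 12000, N_K: 16000}
  NC:  {N_min: 50,  N_2015: 1800,  N_K: 3600}
  TO:  {N_min: 40,  N_2015: 1200,  N_K: 2600}
  CrI: {N_min: 25,  N_2015: 400,   N_K: 1000}
  FP:  {N_min: 40,  N_2015: 600,   N_K: 1400}
  CO:  {N_min: 100, N_2015: 3300,  N_K: 6000}
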