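# Default exposure-parameter sets for the three cohorts (USEPA intake model).
# AT days, EF days/year, ED years, BW kg, IR L/day, RfD mg/kg/day.
children:
  AT: 1460
  EF: 365
  ED: 4
  BW: 15
  IR: 0.78
  RfD: 0.06
teenagers:
  AT: 4745
  EF: 365
  ED: 13
  BW: 50
  IR: 2
  RfD: 0.06
adults:
  AT: 14600
  EF: 365
  ED: 40
  BW: 78
  IR: 2.5
  RfD: 0.06
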