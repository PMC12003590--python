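# Default PK model specs (package defaults: plausible typical values for
# the stated model structures, editable per application).  All rates on a
# day time axis; volumes in L; concentrations come out in mg/L.
mouse_iv:
  # two-compartment disposition, i.v. bolus dosing
  v_central: 0.02
  k_elim: 180.0
  n_compartments: 2
  k12: 2.0
  k21: 3.0
  absorption: iv
  time_unit: day
mouse_ip:
  # same disposition with a first-order absorption compartment for i.p.
  v_central: 0.02
  k_elim: 180.0
  n_compartments: 2
  k12: 2.0
  k21: 3.0
  absorption: first_order
  ka: 10.0
  bioavailability: 1.0
  time_unit: day
mouse_oral:
  v_central: 0.05
  k_elim: 8.0
  n_compartments: 2
  k12: 1.5
  k21: 2.0
  absorption: first_order
  ka: 6.0
  bioavailability: 0.8
  time_unit: day
human_gemcitabine:
  # rapidly cleared nucleoside analog: two-compartment i.v. disposition
  v_central: 15.0
  k_elim: 240.0
  n_compartments: 2
  k12: 40.0
  k21: 60.0
  absorption: iv
  time_unit: day
human_sorafenib:
  # slow oral kinase inhibitor: transit-chain absorption (4 stages) into a
  # one-compartment disposition with a ~30 h half-life
  v_central: 200.0
  k_elim: 0.55
  n_compartments: 1
  absorption: transit
  transit_n: 4
  ktr: 8.0
  bioavailability: 0.44
  time_unit: day
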