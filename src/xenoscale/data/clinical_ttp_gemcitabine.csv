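# Median time to progression (months) with 90% CI in advanced pancreatic
# cancer patients receiving single-agent gemcitabine (weekly 1000 mg/m2),
# digitized from the cited clinical trial publications.
reference,n_patients,median_ttp_months,ci90_low,ci90_high
Hong,56,3.9,3.2,6.7
Kindler,316,7.5,6.2,7.8
Nakai,53,4.7,2.2,6.6
Ozaka,59,5.6,3.3,7.1
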