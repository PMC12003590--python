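# Median time to progression (months) with 90% CI in hepatocellular
# carcinoma patients (Asian populations) receiving sorafenib 400 mg twice
# daily, digitized from the cited clinical trial publications.
reference,n_patients,median_ttp_months,ci90_low,ci90_high
Park,169,3.6,3.1,3.8
Qin,331,3.6,3.1,3.7
Kudo,103,3.5,2.7,4.3
Lyu,132,4.3,3.7,4.9
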