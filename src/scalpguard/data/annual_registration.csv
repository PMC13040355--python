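year,outpatient_volume,appointment_volume
2020,649968,239347
2021,756258,387257
2022,832654,429349
2023,872365,518889
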