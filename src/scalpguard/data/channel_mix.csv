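year,online_pct,onsite_pct,telephone_pct
2020,65.6,28.5,5.9
2021,79.9,18.2,1.9
2022,92.5,7.3,0.2
2023,94.5,5.4,0.1
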