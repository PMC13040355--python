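year,n,completion_rate_pct,no_show_rate_pct
2019,61624,64.6,35.4
2020,88501,68.5,31.5
2021,106200,64.6,35.4
2022,96052,78.0,22.0
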