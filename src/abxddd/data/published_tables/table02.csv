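aware,ddds,cost_inr,printed_ddd_share_pct,printed_cost_share_pct,printed_cost_per_ddd_inr
Access,69500000,11600000000,26.5,15.4,167.5
Watch,133700000,39600000000,50.9,52.3,296.2
Reserve,1600000,4500000000,0.61,5.9,2798.8
Discouraged,57700000,19900000000,21.9,26.3,345.0
NotListed,18520,36100000,0.01,0.05,1951.8
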